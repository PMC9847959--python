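# Recovery times (days) from first positive to first negative COVID-19 PCR test, 50 males over 60 years old (Israeli Ministry of Health, anonymized).
# n = 50
16
16
16
14
36
9
10
11
8
9
12
10
22
5
11
17
20
12
29
12
15
25
25
24
18
13
44
14
20
19
11
10
18
21
31
9
29
12
10
10
13
12
19
33
37
16
63
9
28
16
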