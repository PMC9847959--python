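# Daily ozone level measurements, New York, May-September 1973 (ppb).
# n = 116
41
36
12
18
28
23
19
8
7
16
11
14
18
14
34
6
30
11
1
11
4
32
23
45
115
37
29
71
39
23
21
37
20
12
13
135
49
32
64
40
77
97
97
85
10
27
7
48
35
61
79
63
16
80
108
20
52
82
50
64
59
39
9
16
78
35
66
122
89
110
44
28
65
22
59
23
31
44
21
9
45
168
73
76
118
84
85
96
78
73
91
47
32
20
23
21
24
44
21
28
9
13
46
18
13
24
16
13
23
36
7
14
30
14
18
20
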