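# Successive failures of the air conditioning systems of a fleet of 13 Boeing 720 jet airplanes (hours).
# n = 213
194
413
90
74
55
23
97
50
359
50
130
487
102
15
14
10
57
320
261
51
44
9
254
493
18
209
41
58
60
48
56
87
11
102
12
5
100
14
29
37
186
29
104
7
4
72
270
283
7
57
33
100
61
502
220
120
141
22
603
35
98
54
181
65
49
12
239
14
18
39
3
12
5
32
9
14
70
47
62
142
3
104
85
67
169
24
21
246
47
68
15
2
91
59
447
56
29
176
225
77
197
438
43
134
184
20
386
182
71
80
188
230
152
36
79
59
33
246
1
79
3
27
201
84
27
21
16
88
130
14
118
44
15
42
106
46
230
59
153
104
20
206
5
66
34
29
26
35
5
82
5
61
31
118
326
12
54
36
34
18
25
120
31
22
18
156
11
216
139
67
310
3
46
210
57
76
14
111
97
62
26
71
39
30
7
44
11
63
23
22
23
14
18
13
34
62
11
191
14
16
18
130
90
163
208
1
24
70
16
101
52
208
95
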