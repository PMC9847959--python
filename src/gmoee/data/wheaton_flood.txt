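# Exceedances of flood peaks (m^3/s) of the Wheaton River near Carcross, Yukon Territory, Canada.
# n = 72
1.7
2.2
14.4
1.1
0.4
20.6
5.3
0.7
1.9
13.0
12.0
9.3
1.4
18.7
8.5
25.5
11.6
14.1
22.1
1.1
2.5
14.4
1.7
37.6
0.6
2.2
39.0
0.3
15.0
11.0
7.3
22.9
1.7
0.1
1.1
0.6
9.0
1.7
7.0
20.1
0.4
2.8
14.1
9.9
10.4
10.7
30.0
3.6
5.6
30.8
13.3
4.2
25.5
3.4
11.9
21.5
27.6
36.4
2.7
64.0
1.5
2.5
27.4
1.0
27.1
20.2
16.8
5.3
9.7
27.5
2.5
27.0
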