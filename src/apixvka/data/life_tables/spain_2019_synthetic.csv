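age,qx
0,0.000007
1,0.000008
2,0.000009
3,0.000010
4,0.000011
5,0.000012
6,0.000013
7,0.000015
8,0.000017
9,0.000019
10,0.000021
11,0.000023
12,0.000026
13,0.000029
14,0.000032
15,0.000036
16,0.000040
17,0.000045
18,0.000050
19,0.000056
20,0.000062
21,0.000070
22,0.000078
23,0.000087
24,0.000097
25,0.000108
26,0.000121
27,0.000135
28,0.000151
29,0.000168
30,0.000188
31,0.000210
32,0.000234
33,0.000261
34,0.000291
35,0.000325
36,0.000363
37,0.000405
38,0.000453
39,0.000505
40,0.000564
41,0.000629
42,0.000703
43,0.000784
44,0.000875
45,0.000977
46,0.001091
47,0.001217
48,0.001359
49,0.001517
50,0.001693
51,0.001890
52,0.002109
53,0.002354
54,0.002628
55,0.002933
56,0.003273
57,0.003653
58,0.004077
59,0.004550
60,0.005078
61,0.005666
62,0.006323
63,0.007056
64,0.007873
65,0.008784
66,0.009801
67,0.010934
68,0.012198
69,0.013606
70,0.015176
71,0.016926
72,0.018875
73,0.021047
74,0.023465
75,0.026158
76,0.029154
77,0.032489
78,0.036197
79,0.040320
80,0.044902
81,0.049991
82,0.055639
83,0.061904
84,0.068849
85,0.076540
86,0.085051
87,0.094459
88,0.104847
89,0.116301
90,0.128915
91,0.142783
92,0.158002
93,0.174673
94,0.192892
95,0.212755
96,0.234351
97,0.257759
98,0.283045
99,0.310254
100,1.000000
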