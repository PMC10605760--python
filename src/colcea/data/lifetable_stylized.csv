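# Stylized Gompertz life table: q(age) = min(1, A*exp(B*age)),
# A=0.0001, B=0.085.
age,q_annual
0,0.000100
1,0.000109
2,0.000119
3,0.000129
4,0.000140
5,0.000153
6,0.000167
7,0.000181
8,0.000197
9,0.000215
10,0.000234
11,0.000255
12,0.000277
13,0.000302
14,0.000329
15,0.000358
16,0.000390
17,0.000424
18,0.000462
19,0.000503
20,0.000547
21,0.000596
22,0.000649
23,0.000706
24,0.000769
25,0.000837
26,0.000912
27,0.000992
28,0.001080
29,0.001176
30,0.001281
31,0.001394
32,0.001518
33,0.001653
34,0.001799
35,0.001959
36,0.002133
37,0.002322
38,0.002528
39,0.002752
40,0.002996
41,0.003262
42,0.003552
43,0.003867
44,0.004210
45,0.004583
46,0.004990
47,0.005433
48,0.005915
49,0.006439
50,0.007011
51,0.007632
52,0.008310
53,0.009047
54,0.009849
55,0.010723
56,0.011675
57,0.012710
58,0.013838
59,0.015066
60,0.016402
61,0.017857
62,0.019442
63,0.021166
64,0.023044
65,0.025089
66,0.027314
67,0.029738
68,0.032376
69,0.035248
70,0.038375
71,0.041780
72,0.045486
73,0.049522
74,0.053915
75,0.058699
76,0.063906
77,0.069576
78,0.075748
79,0.082468
80,0.089785
81,0.097750
82,0.106422
83,0.115864
84,0.126143
85,0.137334
86,0.149518
87,0.162782
88,0.177224
89,0.192947
90,0.210065
91,0.228701
92,0.248991
93,0.271080
94,0.295130
95,0.321313
96,0.349819
97,0.380854
98,0.414642
99,0.451428
100,0.491477
101,0.535079
102,0.582550
103,0.634232
104,0.690499
105,0.751758
106,0.818452
107,0.891063
108,0.970115
109,1.000000
110,1.000000
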