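age,annual_death_probability
40,0.000630
41,0.000702
42,0.000783
43,0.000873
44,0.000973
45,0.001085
46,0.001209
47,0.001348
48,0.001503
49,0.001676
50,0.001868
51,0.002083
52,0.002322
53,0.002588
54,0.002886
55,0.003217
56,0.003586
57,0.003998
58,0.004457
59,0.004969
60,0.005540
61,0.006176
62,0.006885
63,0.007676
64,0.008557
65,0.009540
66,0.010635
67,0.011856
68,0.013218
69,0.014736
70,0.016428
71,0.018314
72,0.020417
73,0.022761
74,0.025375
75,0.028289
76,0.031537
77,0.035158
78,0.039196
79,0.043696
80,0.048714
81,0.054308
82,0.060544
83,0.067496
84,0.075246
85,0.083886
86,0.093519
87,0.104258
88,0.116229
89,0.129576
90,0.144454
91,0.161042
92,0.179534
93,0.200149
94,0.223132
95,0.248754
96,0.277318
97,0.309162
98,0.344662
99,0.384239
100,0.428360
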