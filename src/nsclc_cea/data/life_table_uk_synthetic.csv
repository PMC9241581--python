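# synthetic Gompertz-Makeham life table (a=0.0005, b=0.09, c=3.31e-05);
# stands in for the national life table, which is not shipped
age,annual_mortality_probability
40,0.001710
41,0.001824
42,0.001948
43,0.002085
44,0.002234
45,0.002397
46,0.002575
47,0.002771
48,0.002984
49,0.003218
50,0.003474
51,0.003753
52,0.004059
53,0.004393
54,0.004759
55,0.005160
56,0.005597
57,0.006076
58,0.006599
59,0.007172
60,0.007798
61,0.008483
62,0.009231
63,0.010049
64,0.010944
65,0.011922
66,0.012991
67,0.014159
68,0.015436
69,0.016831
70,0.018355
71,0.020020
72,0.021838
73,0.023824
74,0.025992
75,0.028359
76,0.030943
77,0.033761
78,0.036836
79,0.040189
80,0.043845
81,0.047829
82,0.052169
83,0.056895
84,0.062039
85,0.067635
86,0.073721
87,0.080333
88,0.087515
89,0.095309
90,0.103760
91,0.112917
92,0.122829
93,0.133547
94,0.145125
95,0.157616
96,0.171075
97,0.185554
98,0.201108
99,0.217786
100,0.235637
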