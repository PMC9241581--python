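# synthetic Gompertz-Makeham life table (a=0.0008, b=0.092, c=3e-05);
# stands in for the national life table, which is not shipped
age,annual_mortality_probability
40,0.001987
41,0.002102
42,0.002227
43,0.002365
44,0.002515
45,0.002680
46,0.002862
47,0.003060
48,0.003278
49,0.003516
50,0.003777
51,0.004064
52,0.004378
53,0.004722
54,0.005099
55,0.005512
56,0.005965
57,0.006462
58,0.007006
59,0.007602
60,0.008255
61,0.008970
62,0.009754
63,0.010613
64,0.011553
65,0.012583
66,0.013712
67,0.014947
68,0.016300
69,0.017780
70,0.019402
71,0.021176
72,0.023117
73,0.025241
74,0.027565
75,0.030106
76,0.032884
77,0.035921
78,0.039239
79,0.042865
80,0.046823
81,0.051145
82,0.055860
83,0.061003
84,0.066610
85,0.072718
86,0.079368
87,0.086605
88,0.094474
89,0.103023
90,0.112304
91,0.122368
92,0.133272
93,0.145070
94,0.157821
95,0.171582
96,0.186410
97,0.202363
98,0.219494
99,0.237854
100,0.257486
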