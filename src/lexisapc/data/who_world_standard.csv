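age_low,weight
0,0.0886
5,0.0869
10,0.0860
15,0.0847
20,0.0822
25,0.0793
30,0.0761
35,0.0715
40,0.0659
45,0.0604
50,0.0537
55,0.0455
60,0.0372
65,0.0296
70,0.0221
75,0.0152
80,0.0091
85,0.0044
90,0.0015
95,0.0004
100,0.00005
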