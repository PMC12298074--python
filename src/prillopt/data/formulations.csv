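sample,nc,kgm_conc,alg_conc,p_outer,p_inner,airflow,prilling_score,feret_mm,circularity,core_score,coating_mm
1,B,0.7,0.75,0.4,0.6,2.2,2,1.474,0.952,4,0.298
2,C,0.6,1.25,0.8,1.0,2.65,2,1.324,0.918,3,0.074
3,A,0.7,0.75,1.2,0.2,1.75,0,2.417,0.738,0,0.0
4,A,0.6,1.25,0.8,0.2,1.75,*,*,*,*,*
5,B,0.7,0.75,0.4,0.6,2.65,1,1.384,0.929,1,0.306
6,C,0.6,1.25,1.2,1.0,2.2,1,1.769,0.905,3,0.307
7,A,0.6,1.25,0.8,0.2,2.65,*,*,*,*,*
8,B,0.7,0.75,0.4,0.8,1.75,2,1.477,0.946,1,0.323
9,C,0.7,0.75,1.2,1.0,2.2,2,1.44,0.882,3,0.091
10,A,0.6,1.25,0.4,0.6,1.75,*,*,*,*,*
11,B,0.7,1.25,1.2,1.0,2.2,1,2.408,0.742,0,0.0
12,C,0.6,0.75,0.8,0.2,2.65,2,1.681,0.825,5,0.17
13,C,0.7,1.25,0.4,1.0,2.65,2,1.428,0.891,0,0.0
14,A,0.6,0.75,0.8,0.2,2.2,2,1.599,0.823,1,0.395
15,B,0.6,0.75,1.2,0.6,1.75,*,*,*,*,*
16,A,0.7,1.25,0.8,0.6,1.75,0,1.61,0.915,0,0.0
17,B,0.7,0.75,1.2,0.8,2.2,2,3.022,0.642,0,0.0
18,C,0.6,1.25,0.8,0.6,2.65,2,1.216,0.902,3,0.089
19,A,0.6,1.25,1.2,0.2,2.2,*,*,*,*,*
20,B,0.7,0.75,0.8,0.8,2.65,2,1.107,0.944,2,0.254
21,C,0.7,0.75,0.4,1.0,1.75,2,1.486,0.924,0,0.0
22,B,0.6,1.25,0.4,0.2,2.65,*,*,*,*,*
23,A,0.6,0.75,1.2,1.0,2.2,0,1.909,0.829,2,0.343
24,C,0.7,1.25,0.8,0.6,1.75,2,1.707,0.916,4,0.139
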