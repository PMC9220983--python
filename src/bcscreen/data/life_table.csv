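age,hazard
0,0.000312
1,0.00031333
2,0.0003148
3,0.00031644
4,0.00031826
5,0.00032029
6,0.00032253
7,0.00032503
8,0.0003278
9,0.00033087
10,0.00033429
11,0.00033809
12,0.00034231
13,0.00034699
14,0.00035219
15,0.00035797
16,0.00036439
17,0.00037151
18,0.00037943
19,0.00038823
20,0.00039799
21,0.00040884
22,0.00042089
23,0.00043428
24,0.00044914
25,0.00046565
26,0.00048399
27,0.00050436
28,0.00052699
29,0.00055212
30,0.00058003
31,0.00061104
32,0.00064547
33,0.00068372
34,0.0007262
35,0.00077338
36,0.00082579
37,0.000884
38,0.00094866
39,0.00102047
40,0.00110024
41,0.00118883
42,0.00128723
43,0.00139653
44,0.00151793
45,0.00165277
46,0.00180253
47,0.00196888
48,0.00215364
49,0.00235886
50,0.0025868
51,0.00283997
52,0.00312117
53,0.0034335
54,0.00378041
55,0.00416573
56,0.00459371
57,0.00506907
58,0.00559706
59,0.0061835
60,0.00683486
61,0.00755834
62,0.00836192
63,0.00925446
64,0.01024581
65,0.01134692
66,0.01256993
67,0.01392834
68,0.01543714
69,0.01711298
70,0.01897436
71,0.02104181
72,0.02333815
73,0.02588871
74,0.02872166
75,0.03186823
76,0.03536317
77,0.03924504
78,0.04355667
79,0.04834564
80,0.0536648
81,0.05957285
82,0.06613498
83,0.07342362
84,0.08151918
85,0.090511
86,0.10049831
87,0.11159133
88,0.12391246
89,0.13759767
90,0.15279798
91,0.16968113
92,0.18843342
93,0.20926178
94,0.23239607
95,0.25809156
96,0.28663183
97,0.3183318
98,0.35354129
99,0.39264885
100,0.43608603
101,0.48433217
102,0.53791967
103,0.59743987
104,0.66354959
105,0.73697835
106,0.81853646
107,0.90912392
108,1.00974037
109,1.12149613
110,1.24562444
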