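# SYNTHETIC arterial tree generated by stenoflow.fixtures - plausible but NON-ANATOMICAL geometry, not derived from any published segment table.
# 103-segment refinement of the default tree (seed 0)
id,parent_id,length_cm,area_prox_cm2,area_dist_cm2,p0_mmhg,p1_mmhg,visc_coeff,terminal_r1,terminal_r2,terminal_ct
0,,1.9815829,5.3290359,5.1782141,70,61.511073,0,,,
1,0,1.9815829,5.1782141,5.0273923,70,61.511073,0,,,
2,1,1.4709917,4.7118669,4.5646211,70,74.8005,0,,,
3,2,1.4709917,4.5646211,4.4173752,70,74.8005,0,,,
4,3,1.5247653,4.3538825,4.1007498,70,87.94343,0,,,
5,4,1.5247653,4.1007498,3.8476171,70,87.94343,0,,,
6,5,1.6819664,3.6153556,3.4145025,70,101.29672,0,,,
7,6,1.6819664,3.4145025,3.2136494,70,101.29672,0,,,
8,7,1.6819664,3.2136494,3.0127963,70,101.29672,0,,,
9,8,1.6956715,2.804886,2.67132,70,115.01848,0,,,
10,9,1.6956715,2.67132,2.537754,70,115.01848,0,,,
11,10,1.6956715,2.537754,2.404188,70,115.01848,0,,,
12,11,2.4502739,2.2277951,2.0252683,70,129.19332,0,,,
13,12,2.4502739,2.0252683,1.8227415,70,129.19332,0,,,
14,13,2.4533586,1.7243035,1.5721591,70,143.8719,0,,,
15,14,2.4533586,1.5721591,1.4200146,70,143.8719,0,,,
16,15,2.4675656,1.3119421,1.2110235,70,162.19633,0,,,
17,16,2.4675656,1.2110235,1.1101048,70,162.19633,0,,,
18,1,2.5041461,0.50726358,0.49035479,70,194.5481,0,,,
19,18,2.5041461,0.49035479,0.47344601,70,194.5481,0,,,
20,19,2.5041461,0.47344601,0.45653722,70,194.5481,0,,,
21,20,2.5041461,0.45653722,0.43962843,70,194.5481,0,,,
22,21,2.5041461,0.43962843,0.42271965,70,194.5481,0,,,
23,22,2.5041461,0.42271965,0.40581086,70,194.5481,0,1.2734847,11.351515,0.043564356
24,1,2.4922687,0.54559366,0.49599424,70,194.5481,0,,,
25,24,2.4922687,0.49599424,0.44639481,70,194.5481,0,,,
26,25,2.2982664,0.12754726,0.1226416,70,305.91033,0,,,
27,26,2.2982664,0.1226416,0.11773593,70,305.91033,0,,,
28,27,2.2982664,0.11773593,0.11283027,70,305.91033,0,,,
29,28,2.2982664,0.11283027,0.10792461,70,305.91033,0,,,
30,29,2.2982664,0.10792461,0.10301894,70,305.91033,0,,,
31,30,2.2982664,0.10301894,0.098113279,70,305.91033,0,6.482854,27.183813,0.016336634
32,25,2.514719,0.40272999,0.38762762,70,305.91033,0,,,
33,32,2.514719,0.38762762,0.37252524,70,305.91033,0,,,
34,33,2.514719,0.37252524,0.35742287,70,305.91033,0,,,
35,34,2.514719,0.35742287,0.34232049,70,305.91033,0,,,
36,35,2.514719,0.34232049,0.32721812,70,305.91033,0,,,
37,36,2.514719,0.32721812,0.31211574,70,305.91033,0,,,
38,37,2.514719,0.31211574,0.29701337,70,305.91033,0,,,
39,38,2.514719,0.29701337,0.28191099,70,305.91033,0,,,
40,39,2.514719,0.28191099,0.26680862,70,305.91033,0,,,
41,40,2.514719,0.26680862,0.25170624,70,305.91033,0,2.5269697,14.306364,0.032673267
42,3,2.4883678,0.5023077,0.48556411,70,194.5481,0,,,
43,42,2.4883678,0.48556411,0.46882052,70,194.5481,0,,,
44,43,2.4883678,0.46882052,0.45207693,70,194.5481,0,,,
45,44,2.4883678,0.45207693,0.43533334,70,194.5481,0,,,
46,45,2.4883678,0.43533334,0.41858975,70,194.5481,0,,,
47,46,2.4883678,0.41858975,0.40184616,70,194.5481,0,1.2860492,11.338951,0.043564356
48,3,1.6987224,0.56093862,0.52694234,70,194.5481,0,,,
49,48,1.6987224,0.52694234,0.49294606,70,194.5481,0,,,
50,49,1.6987224,0.49294606,0.45894978,70,194.5481,0,,,
51,50,2.3473762,0.13096482,0.12592771,70,305.91033,0,,,
52,51,2.3473762,0.12592771,0.1208906,70,305.91033,0,,,
53,52,2.3473762,0.1208906,0.11585349,70,305.91033,0,,,
54,53,2.3473762,0.11585349,0.11081638,70,305.91033,0,,,
55,54,2.3473762,0.11081638,0.10577928,70,305.91033,0,,,
56,55,2.3473762,0.10577928,0.10074217,70,305.91033,0,6.3136825,27.352984,0.016336634
57,50,2.4888921,0.40301515,0.38790208,70,305.91033,0,,,
58,57,2.4888921,0.38790208,0.37278901,70,305.91033,0,,,
59,58,2.4888921,0.37278901,0.35767594,70,305.91033,0,,,
60,59,2.4888921,0.35767594,0.34256288,70,305.91033,0,,,
61,60,2.4888921,0.34256288,0.32744981,70,305.91033,0,,,
62,61,2.4888921,0.32744981,0.31233674,70,305.91033,0,,,
63,62,2.4888921,0.31233674,0.29722367,70,305.91033,0,,,
64,63,2.4888921,0.29722367,0.2821106,70,305.91033,0,,,
65,64,2.4888921,0.2821106,0.26699754,70,305.91033,0,,,
66,65,2.4888921,0.26699754,0.25188447,70,305.91033,0,2.5251818,14.308152,0.032673267
67,8,1.5132893,0.59124232,0.54197212,70,229.24864,0,,,
68,67,1.5132893,0.54197212,0.49270193,70,229.24864,0,1.1222222,4.4888889,0.098019802
69,11,2.4810242,0.45045638,0.42543102,70,229.24864,0,,,
70,69,2.4810242,0.42543102,0.40040567,70,229.24864,0,1.3899586,7.0267081,0.065346535
71,13,1.5233693,0.29983002,0.27484419,70,266.35733,0,,,
72,71,1.5233693,0.27484419,0.24985835,70,266.35733,0,2.02,8.08,0.054455446
73,13,1.4914677,0.30520852,0.27977448,70,266.35733,0,,,
74,73,1.4914677,0.27977448,0.25434044,70,266.35733,0,2.02,8.08,0.054455446
75,17,1.9857496,0.45128754,0.42621601,70,305.91033,0,,,
76,75,1.9857496,0.42621601,0.40114448,70,305.91033,0,,,
77,76,1.9857496,0.40114448,0.37607295,70,305.91033,0,,,
78,77,1.9857496,0.37607295,0.35100142,70,305.91033,0,,,
79,78,2.4837911,0.32120704,0.30916178,70,392.43501,0,,,
80,79,2.4837911,0.30916178,0.29711651,70,392.43501,0,,,
81,80,2.4837911,0.29711651,0.28507125,70,392.43501,0,,,
82,81,2.4837911,0.28507125,0.27302598,70,392.43501,0,,,
83,82,2.4837911,0.27302598,0.26098072,70,392.43501,0,,,
84,83,2.4837911,0.26098072,0.24893546,70,392.43501,0,,,
85,84,2.4837911,0.24893546,0.23689019,70,392.43501,0,,,
86,85,2.4837911,0.23689019,0.22484493,70,392.43501,0,,,
87,86,2.4837911,0.22484493,0.21279966,70,392.43501,0,,,
88,87,2.4837911,0.21279966,0.2007544,70,392.43501,0,2.3764706,9.5058824,0.046287129
89,17,2.0312219,0.44804914,0.42315752,70,305.91033,0,,,
90,89,2.0312219,0.42315752,0.3982659,70,305.91033,0,,,
91,90,2.0312219,0.3982659,0.37337429,70,305.91033,0,,,
92,91,2.0312219,0.37337429,0.34848267,70,305.91033,0,,,
93,92,2.5123187,0.31650762,0.30463858,70,392.43501,0,,,
94,93,2.5123187,0.30463858,0.29276955,70,392.43501,0,,,
95,94,2.5123187,0.29276955,0.28090051,70,392.43501,0,,,
96,95,2.5123187,0.28090051,0.26903147,70,392.43501,0,,,
97,96,2.5123187,0.26903147,0.25716244,70,392.43501,0,,,
98,97,2.5123187,0.25716244,0.2452934,70,392.43501,0,,,
99,98,2.5123187,0.2452934,0.23342437,70,392.43501,0,,,
100,99,2.5123187,0.23342437,0.22155533,70,392.43501,0,,,
101,100,2.5123187,0.22155533,0.2096863,70,392.43501,0,,,
102,101,2.5123187,0.2096863,0.19781726,70,392.43501,0,2.3764706,9.5058824,0.046287129
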