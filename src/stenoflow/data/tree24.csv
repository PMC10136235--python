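# SYNTHETIC arterial tree generated by stenoflow.fixtures - plausible but NON-ANATOMICAL geometry, not derived from any published segment table.
# 24-segment default systemic tree (seed 0)
id,parent_id,length_cm,area_prox_cm2,area_dist_cm2,p0_mmhg,p1_mmhg,visc_coeff,terminal_r1,terminal_r2,terminal_ct
0,,3.9631659,5.3290359,5.0273923,70,61.511073,0,,,
1,0,2.9419833,4.7118669,4.4173752,70,74.8005,0,,,
2,1,3.0495307,4.3538825,3.8476171,70,87.94343,0,,,
3,2,5.0458993,3.6153556,3.0127963,70,101.29672,0,,,
4,3,5.0870145,2.804886,2.404188,70,115.01848,0,,,
5,4,4.9005477,2.2277951,1.8227415,70,129.19332,0,,,
6,5,4.9067171,1.7243035,1.4200146,70,143.8719,0,,,
7,6,4.9351311,1.3119421,1.1101048,70,162.19633,0,,,
8,0,15.024877,0.50726358,0.40581086,70,194.5481,0,1.2734847,11.351515,0.043564356
9,0,4.9845374,0.54559366,0.44639481,70,194.5481,0,,,
10,9,13.789599,0.12754726,0.098113279,70,305.91033,0,6.482854,27.183813,0.016336634
11,9,25.14719,0.40272999,0.25170624,70,305.91033,0,2.5269697,14.306364,0.032673267
12,1,14.930207,0.5023077,0.40184616,70,194.5481,0,1.2860492,11.338951,0.043564356
13,1,5.0961671,0.56093862,0.45894978,70,194.5481,0,,,
14,13,14.084257,0.13096482,0.10074217,70,305.91033,0,6.3136825,27.352984,0.016336634
15,13,24.888921,0.40301515,0.25188447,70,305.91033,0,2.5251818,14.308152,0.032673267
16,3,3.0265786,0.59124232,0.49270193,70,229.24864,0,1.1222222,4.4888889,0.098019802
17,4,4.9620484,0.45045638,0.40040567,70,229.24864,0,1.3899586,7.0267081,0.065346535
18,5,3.0467385,0.29983002,0.24985835,70,266.35733,0,2.02,8.08,0.054455446
19,5,2.9829354,0.30520852,0.25434044,70,266.35733,0,2.02,8.08,0.054455446
20,7,7.9429982,0.45128754,0.35100142,70,305.91033,0,,,
21,20,24.837911,0.32120704,0.2007544,70,392.43501,0,2.3764706,9.5058824,0.046287129
22,7,8.1248878,0.44804914,0.34848267,70,305.91033,0,,,
23,22,25.123187,0.31650762,0.19781726,70,392.43501,0,2.3764706,9.5058824,0.046287129
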