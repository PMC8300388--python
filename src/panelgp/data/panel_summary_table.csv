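snp_level,method,sigma_d2_1e10,r2_mean,r2_var,acc_FP,acc_MY,acc_SCS
1,PhyD,0.245,0.047,0.005,0.704,0.645,0.482
1,GenD,867.650,0.027,0.011,0.594,0.599,0.394
1,RanD,639.753,0.097,0.038,0.523,0.589,0.459
2,PhyD,0.216,0.061,0.012,0.710,0.667,0.531
2,GenD,226.149,0.030,0.014,0.603,0.630,0.458
2,RanD,158.043,0.125,0.053,0.611,0.647,0.527
3,PhyD,0.240,0.082,0.021,0.761,0.703,0.563
3,GenD,97.622,0.029,0.014,0.630,0.645,0.491
3,RanD,72.558,0.164,0.075,0.605,0.659,0.553
4,PhyD,0.268,0.088,0.023,0.732,0.704,0.610
4,GenD,52.830,0.030,0.015,0.663,0.666,0.523
4,RanD,43.857,0.193,0.091,0.617,0.662,0.576
5,PhyD,0.242,0.108,0.034,0.753,0.706,0.621
5,GenD,32.881,0.030,0.015,0.656,0.677,0.539
5,RanD,28.646,0.219,0.103,0.608,0.668,0.590
7,PhyD,0.218,0.138,0.049,0.775,0.720,0.624
7,GenD,16.006,0.029,0.014,0.652,0.694,0.569
7,RanD,15.380,0.253,0.117,0.709,0.703,0.601
10,PhyD,0.212,0.191,0.077,0.759,0.724,0.628
10,GenD,6.754,0.029,0.013,0.626,0.692,0.604
10,RanD,8.399,0.306,0.138,0.686,0.700,0.612
15,PhyD,0.170,0.275,0.114,0.771,0.725,0.640
15,GenD,2.976,0.031,0.010,0.641,0.697,0.638
15,RanD,4.266,0.373,0.157,0.686,0.703,0.623
20,PhyD,0.157,0.323,0.131,0.763,0.727,0.643
20,GenD,1.798,0.050,0.009,0.627,0.695,0.650
20,RanD,2.627,0.420,0.167,0.718,0.712,0.628
30,PhyD,0.128,0.398,0.152,0.765,0.726,0.648
30,GenD,0.974,0.110,0.024,0.679,0.710,0.652
30,RanD,1.314,0.479,0.174,0.668,0.697,0.640
50,PhyD,0.098,0.476,0.167,0.761,0.726,0.650
50,GenD,0.485,0.238,0.075,0.698,0.712,0.652
50,RanD,0.551,0.553,0.176,0.715,0.710,0.643
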