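# Synthetic reconstruction of the ROC-area correlation lookup table.
# Maps the average inter-test score correlation (rows, rho) and the average
# of the two ROC areas (columns) to the correlation r between the two AUC
# estimates from the same subjects.  The anchor rows rho = 0.3, 0.5, 0.8 are
# calibrated so that the continuous-data sample-size pipeline reproduces the
# published scenario tables for a baseline AUC of 0.80; the
# remaining rows are monotone (PCHIP) interpolants between r = 0 at rho = 0
# and r = 1 at rho = 1.  This file is generated, not digitized from the
# original reference.
rho,0.700,0.725,0.750,0.775,0.800,0.825,0.850,0.875,0.900
0.0,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000
0.1,0.0852,0.0848,0.0844,0.0839,0.0833,0.0826,0.0818,0.0805,0.0789
0.2,0.1732,0.1726,0.1719,0.1710,0.1699,0.1687,0.1669,0.1646,0.1614
0.3,0.2638,0.2630,0.2620,0.2608,0.2593,0.2576,0.2550,0.2515,0.2470
0.4,0.3572,0.3563,0.3551,0.3537,0.3519,0.3498,0.3462,0.3414,0.3356
0.5,0.4542,0.4532,0.4520,0.4505,0.4486,0.4463,0.4420,0.4365,0.4300
0.6,0.5536,0.5527,0.5516,0.5502,0.5485,0.5465,0.5426,0.5377,0.5318
0.7,0.6558,0.6551,0.6543,0.6532,0.6520,0.6505,0.6477,0.6443,0.6398
0.8,0.7632,0.7627,0.7621,0.7614,0.7606,0.7597,0.7580,0.7560,0.7530
0.9,0.8781,0.8779,0.8775,0.8772,0.8768,0.8763,0.8755,0.8745,0.8729
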