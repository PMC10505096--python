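# Simulated crossing kinetics for the 18-compound CNS library.
# k in ns^-1; P_sim in cm/s; sigma columns are +-1 standard deviation.
# Compounds 14-18 have no 127C entries: the rate never converged there.
index,name,k_127C,k_127C_sigma,k_167C,k_167C_sigma,P_sim_127C,P_sim_127C_sigma,P_sim_167C,P_sim_167C_sigma
1,Atenolol,0.010,0.00,0.039,0.00,0.077,0.000,0.700,0.036
2,Bupropion,0.010,0.00,0.112,0.00,0.074,0.000,1.56,0.056
3,Dilantin,0.025,0.01,0.208,0.01,0.184,0.068,2.89,0.139
4,Duloxetine,0.008,0.00,0.032,0.00,0.057,0.000,0.450,0.028
5,Effexor,0.016,0.00,0.142,0.00,0.121,0.000,1.97,0.028
6,Ethanol,0.410,0.01,1.294,0.03,3.08,0.075,8.99,0.181
7,Ibuprofen,0.012,0.00,0.300,0.01,0.090,0.000,2.08,0.069
8,Ketoprofen,0.028,0.00,1.035,0.02,0.212,0.000,7.19,0.139
9,Nadolol,0.016,0.00,0.071,0.01,0.120,0.000,0.650,0.091
10,Naproxen,0.022,0.00,0.860,0.03,0.165,0.000,5.97,0.208
11,Nicotine,0.335,0.01,1.419,0.02,2.51,0.218,9.85,0.111
12,Propanol,0.498,0.01,2.425,0.04,3.74,0.075,16.84,0.299
13,Ritalin,0.087,0.00,0.654,0.02,0.651,0.000,4.54,0.118
14,Caffeine,,,0.006,0.00,,,0.090,0.028
15,Doxorubicin,,,0.003,0.00,,,0.070,0.011
16,Ethosuximide,,,0.087,0.01,,,0.710,0.041
17,Glycerol,,,0.017,0.01,,,0.120,0.036
18,Temozolomide,,,0.018,0.00,,,0.130,0.015
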