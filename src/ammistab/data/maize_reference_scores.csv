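genotype,code,mean,ipca1,ipca2,asv,gsi
SMH_1682,G01,13.11,0.399,-0.053,0.458,75
SMH_16002,G02,13.35,-0.257,0.040,0.296,52
SMH_16041,G03,14.37,0.032,-0.144,0.148,12
SMH_16043,G04,14.73,0.294,0.119,0.356,29
SMH_16045,G05,13.57,-0.228,-0.139,0.294,42
SMH_16048,G06,14.25,-0.617,-0.045,0.705,68
SMH_16086,G07,11.35,0.034,0.329,0.331,89
SMH_16099,G08,13.96,-0.858,-0.100,0.982,84
SMH_16107,G09,14.22,-0.305,0.009,0.348,35
SMH_16129,G10,13.05,0.630,-0.081,0.722,103
SMH_16130,G11,13.87,-0.460,0.102,0.534,64
SMH_16139,G12,12.97,0.287,0.197,0.382,75
SMH_16144,G13,12.72,0.402,0.592,0.748,112
SMH_16145,G14,13.27,-0.457,-0.606,0.799,101
SMH_16164,G15,12.53,0.032,0.193,0.196,62
SMH_16165,G16,11.66,0.113,-0.186,0.226,76
SMH_16201,G17,12.47,0.590,-0.351,0.759,118
SMH_16247,G18,12.56,-0.230,0.020,0.263,67
SMH_16264,G19,13.04,0.239,0.288,0.396,74
SMH_16265,G20,11.71,0.294,0.416,0.534,111
SMH_16266,G21,13.05,0.076,-0.749,0.754,106
SMH_16295,G22,14.07,0.006,-0.174,0.174,19
SMH_16309,G23,13.14,-0.463,-0.222,0.572,90
SMH_16315,G24,12.27,0.370,0.315,0.526,101
SMH_16322,G25,14.03,0.228,0.176,0.313,32
SMH_16334,G26,14.35,-0.294,-0.023,0.335,29
SMH_16337,G27,13.69,-0.605,-0.088,0.695,77
SMH_16379,G28,12.11,0.342,-0.098,0.402,90
SMH_16380,G29,12.75,-0.109,0.133,0.181,57
SMH_16411,G30,12.39,-0.370,-0.125,0.439,88
SMH_16417,G31,10.87,-0.392,0.259,0.516,111
SMH_16453,G32,13.99,0.180,-0.662,0.693,69
SMH_16461,G33,12.21,0.363,-0.233,0.474,95
SMH_16467,G34,11.54,-0.048,-0.536,0.539,116
SMH_16481,G35,11.36,-0.460,0.087,0.532,113
SMH_1701,G36,14.32,0.473,-0.350,0.643,62
SMH_1702,G37,13.12,0.078,-0.189,0.209,50
SMH_1703,G38,13.56,0.223,0.030,0.256,41
SMH_1704,G39,13.34,-0.110,-0.064,0.140,40
SMH_1705,G40,14.01,0.224,-0.359,0.441,47
SMH_1706,G41,14.92,0.076,-0.089,0.124,2
SMH_1707,G42,14.38,0.007,-0.136,0.136,9
SMH_1708,G43,13.51,0.511,0.395,0.704,85
SMH_1709,G44,13.68,0.610,0.065,0.698,80
SMH_1709_A,G45,13.06,-0.156,0.169,0.246,54
SMH_1710,G46,13.92,-0.016,0.130,0.131,18
SMH_1711,G47,14.37,-0.034,-0.127,0.133,10
SMH_1712,G48,13.43,-0.149,-0.471,0.501,70
SMH_1713,G49,13.80,-0.401,0.210,0.503,60
SMH_1714,G50,12.42,0.103,-0.216,0.246,69
SMH_1715,G51,13.57,0.115,0.417,0.437,56
SMH_1716,G52,13.03,0.244,0.367,0.460,82
SMH_1717,G53,12.05,0.204,0.470,0.525,104
SMH_1718,G54,13.69,0.427,0.068,0.491,60
SMH_1719,G55,13.05,-0.057,-0.630,0.634,97
SMH_1720,G56,12.16,-0.297,0.761,0.833,125
SMH_1721,G57,13.30,-0.126,0.483,0.504,76
SMH_1722,G58,13.48,-0.106,0.324,0.346,53
SMH_1723,G59,12.51,-0.742,0.362,0.919,120
SMH_1724,G60,13.81,-0.011,-0.081,0.082,87
SMH_1725,G61,12.03,-0.182,-0.532,0.571,113
SMH_1726,G62,13.49,-0.219,0.230,0.339,51
SMH_1727,G63,13.44,0.177,0.176,0.268,47
SMH_1728,G64,13.86,0.259,0.441,0.530,63
SMH_1729,G65,13.22,0.055,0.115,0.132,40
SMH_1730,G66,12.73,0.075,-0.532,0.538,98
NK Ravello,G67,11.60,0.133,-0.335,0.367,92
Ricardinio,G68,13.42,0.348,-0.192,0.441,65
ES Gallery,G69,14.87,-0.492,0.432,0.707,62
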