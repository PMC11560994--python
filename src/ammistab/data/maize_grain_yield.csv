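genotype,code,Kobierzyce,Mikulice,Płaczkowo,Radzików,Smolice
SMH_1682,G01,12.97,12.99,13.79,13.00,12.78
SMH_16002,G02,13.97,13.72,13.71,13.82,11.54
SMH_16041,G03,14.50,14.23,15.03,14.93,13.15
SMH_16043,G04,14.12,14.85,16.89,14.69,13.13
SMH_16045,G05,13.69,13.84,14.21,14.46,11.65
SMH_16048,G06,14.67,14.69,15.32,15.52,11.06
SMH_16086,G07,11.53,11.78,12.98,11.06,9.41
SMH_16099,G08,15.25,13.52,15.05,15.63,10.34
SMH_16107,G09,15.53,13.10,15.57,14.98,11.93
SMH_16129,G10,12.06,12.67,15.12,13.00,12.41
SMH_16130,G11,14.95,14.15,14.20,14.45,11.60
SMH_16139,G12,13.64,12.33,14.21,12.54,12.11
SMH_16144,G13,13.19,12.50,15.07,11.50,11.35
SMH_16145,G14,13.57,12.68,13.50,15.39,11.20
SMH_16164,G15,13.35,12.59,12.96,12.29,11.45
SMH_16165,G16,10.50,12.42,13.01,12.39,10.00
SMH_16201,G17,11.68,11.16,14.57,13.05,11.87
SMH_16247,G18,13.37,12.76,12.68,12.98,11.01
SMH_16264,G19,13.76,13.16,13.51,12.34,12.43
SMH_16265,G20,12.48,11.94,12.33,10.68,11.13
SMH_16266,G21,12.01,12.64,13.73,14.91,11.94
SMH_16295,G22,14.47,13.69,14.56,14.69,12.96
SMH_16309,G23,14.20,13.14,12.62,14.27,11.47
SMH_16315,G24,13.03,11.97,13.13,11.40,11.81
SMH_16322,G25,15.69,12.55,14.79,13.60,13.52
SMH_16334,G26,15.23,13.91,15.29,15.10,12.22
SMH_16337,G27,15.24,13.18,13.92,14.84,11.29
SMH_16379,G28,11.85,11.88,13.13,12.25,11.43
SMH_16380,G29,13.47,12.63,13.73,12.93,11.00
SMH_16411,G30,12.81,13.62,11.33,13.11,11.06
SMH_16417,G31,11.77,11.78,11.04,10.99,8.76
SMH_16453,G32,13.16,13.59,14.41,15.48,13.32
SMH_16461,G33,12.60,11.43,12.31,12.42,12.31
SMH_16467,G34,11.35,11.19,11.69,12.97,10.49
SMH_16481,G35,12.49,11.82,11.28,11.90,9.34
SMH_1701,G36,14.36,12.81,15.46,14.84,14.12
SMH_1702,G37,13.52,12.44,13.84,13.72,12.08
SMH_1703,G38,13.89,12.97,14.81,13.59,12.51
SMH_1704,G39,13.45,13.26,14.57,14.02,11.38
SMH_1705,G40,14.26,13.06,14.42,14.74,13.59
SMH_1706,G41,15.27,14.51,15.71,15.32,13.79
SMH_1707,G42,14.73,14.27,14.65,14.87,13.35
SMH_1708,G43,13.62,13.70,14.87,12.41,12.98
SMH_1709,G44,13.71,13.21,14.65,13.09,13.76
SMH_1709_A,G45,14.16,12.83,13.76,13.16,11.41
SMH_1710,G46,14.97,12.93,15.42,14.07,12.22
SMH_1711,G47,15.27,13.11,15.53,15.04,12.89
SMH_1712,G48,13.24,12.71,14.63,15.05,11.50
SMH_1713,G49,15.38,13.44,14.51,14.12,11.57
SMH_1714,G50,13.55,11.10,12.59,12.91,11.94
SMH_1715,G51,14.28,13.23,15.57,13.03,11.74
SMH_1716,G52,13.88,12.77,14.16,12.27,12.08
SMH_1717,G53,12.33,11.97,14.49,11.38,10.10
SMH_1718,G54,13.27,13.72,15.12,13.44,12.90
SMH_1719,G55,13.06,12.47,12.80,14.62,12.28
SMH_1720,G56,13.89,13.16,12.50,11.07,10.19
SMH_1721,G57,14.38,14.30,13.34,12.56,11.93
SMH_1722,G58,14.50,13.62,14.25,13.19,11.83
SMH_1723,G59,13.80,12.99,13.81,13.06,8.88
SMH_1724,G60,15.33,12.22,14.46,14.23,12.79
SMH_1725,G61,12.80,10.83,12.01,13.56,10.94
SMH_1726,G62,14.42,13.63,14.30,13.57,11.53
SMH_1727,G63,13.65,13.81,14.18,13.13,12.45
SMH_1728,G64,14.52,13.73,15.41,13.00,12.64
SMH_1729,G65,13.47,13.05,14.72,13.34,11.52
SMH_1730,G66,12.48,12.00,13.33,14.08,11.75
NK Ravello,G67,11.71,11.14,11.81,12.36,10.99
Ricardinio,G68,12.60,13.21,15.06,13.89,12.33
ES Gallery,G69,16.81,15.05,15.15,14.73,12.60
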