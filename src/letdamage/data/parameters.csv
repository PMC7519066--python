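# Built-in parameter database for the analytical LET-dependent DNA damage
# yield models (hand-transcribed from the published parameter tables).
# SB/SSB rows use the decreasing power-law-with-dip form; DSB-family rows
# use the increasing power-law-with-overkill form. NA marks a term omitted
# from the published fit (not a zero).
damage_class,ion,channel,p1,p2,p3,p4,p5
SB,H,TOTAL,170,1.335,0.7023,8.541,6.902
SB,H,DIRECT,64,NA,NA,3.532,12.51
SB,H,INDIRECT,106,1.076,0.8189,5.679,9.223
SB,He,TOTAL,170,0.4632,0.8913,11.81,7.542
SB,He,DIRECT,64,NA,NA,4.015,20.46
SB,He,INDIRECT,106,1.815,0.6758,5.652,13.93
SB,Li,TOTAL,170,0.405,0.8499,12.25,8.795
SB,Li,DIRECT,64,0.004687,3.354,3.525,15.07
SB,Li,INDIRECT,106,1.784,0.6373,6.574,13.43
SB,Be,TOTAL,170,0.6563,0.7454,10.84,7.203
SB,Be,DIRECT,64,0.005799,2.023,4.085,16.17
SB,Be,INDIRECT,106,3.298,0.5625,5.735,13.88
SB,B,TOTAL,170,0.7101,0.7173,10.36,9.02
SB,B,DIRECT,64,0.006684,1.662,3.704,15.59
SB,B,INDIRECT,106,4.198,0.5332,4.87,13.1
SB,C,TOTAL,170,0.9285,0.6785,10.02,9.499
SB,C,DIRECT,64,0.006881,1.621,3.802,16.69
SB,C,INDIRECT,106,6.272,0.5007,4.717,15.26
SB,N,TOTAL,170,0.9985,0.6579,9.627,11.12
SB,N,DIRECT,64,0.006951,1.485,3.747,18.77
SB,N,INDIRECT,106,7.44,0.4832,4.843,17.03
SB,O,TOTAL,170,1.754,0.5993,9.64,8.154
SB,O,DIRECT,64,0.01046,1.168,3.224,19.08
SB,O,INDIRECT,106,14.64,0.4437,3.151,15.89
SB,Ne,TOTAL,170,2.388,0.5616,8.841,9.224
SB,Ne,DIRECT,64,0.009527,1.127,3.748,18.59
SB,Ne,INDIRECT,106,20.28,0.4207,3.219,28.1
SSB,H,TOTAL,156,0.9613,0.9173,10.21,7.124
SSB,H,DIRECT,60,39.79,0.2471,4.189,35.17
SSB,H,INDIRECT,102,2.438,0.7084,4.389,7.916
SSB,He,TOTAL,156,1.681,0.7616,9.093,8.052
SSB,He,DIRECT,60,1.765,0.5268,1.127,1.642
SSB,He,INDIRECT,102,3.242,0.6263,4.999,12.97
SSB,Li,TOTAL,156,1.856,0.7023,9.737,8.993
SSB,Li,DIRECT,60,0.3056,0.7,4.357,8.53
SSB,Li,INDIRECT,102,3.067,0.5961,6.479,13.54
SSB,Be,TOTAL,156,3.771,0.6105,7.937,7.851
SSB,Be,DIRECT,60,0.2586,0.6959,5.034,11.37
SSB,Be,INDIRECT,102,6.137,0.5251,5.421,14.58
SSB,B,TOTAL,156,5.414,0.5695,6.837,8.997
SSB,B,DIRECT,60,0.298,0.6564,4.575,12.74
SSB,B,INDIRECT,102,9.016,0.4909,4.265,14.22
SSB,C,TOTAL,156,9.511,0.5256,5.818,8.409
SSB,C,DIRECT,60,0.3865,0.6131,4.429,16.03
SSB,C,INDIRECT,102,14.25,0.4602,4.069,16.06
SSB,N,TOTAL,156,12.73,0.5006,5.67,8.453
SSB,N,DIRECT,60,0.3666,0.605,4.612,19.38
SSB,N,INDIRECT,102,19,0.4397,4.008,17.7
SSB,O,TOTAL,156,21.17,0.4693,4.926,6.674
SSB,O,DIRECT,60,0.651,0.5414,3.499,20.59
SSB,O,INDIRECT,102,40.6,0.4036,2.215,15.94
SSB,Ne,TOTAL,156,52.47,0.4215,NA,NA
SSB,Ne,DIRECT,60,0.8246,0.5072,3.615,24.24
SSB,Ne,INDIRECT,102,65.9,0.3788,2.26,30.59
DSB,H,TOTAL,6.8,0.1835,0.9583,NA,NA
DSB,H,DIRECT,2.8,0.07011,1.231,NA,NA
DSB,H,INDIRECT,2.2,0.03598,0.5834,NA,NA
DSB,He,TOTAL,6.8,0.1679,0.9704,0.004323,1.359
DSB,He,DIRECT,2.8,0.08076,0.816,NA,NA
DSB,He,INDIRECT,2.2,0.02683,0.6349,0.002725,2.022
DSB,Li,TOTAL,6.8,0.2148,0.864,0.00399,0.9872
DSB,Li,DIRECT,2.8,0.07501,0.7078,NA,NA
DSB,Li,INDIRECT,2.2,0.03443,0.6439,0.002556,1.057
DSB,Be,TOTAL,6.8,0.2148,0.9999,0.009586,1.019
DSB,Be,DIRECT,2.8,0.08651,0.9131,0.003924,0.8367
DSB,Be,INDIRECT,2.2,0.03583,0.7321,0.003678,1.088
DSB,B,TOTAL,6.8,0.2303,0.9711,0.009576,1.016
DSB,B,DIRECT,2.8,0.1168,0.9562,0.009723,0.8111
DSB,B,INDIRECT,2.2,0.03316,0.7289,0.003393,1.133
DSB,C,TOTAL,6.8,0.2052,1.02,0.009922,1.106
DSB,C,DIRECT,2.8,0.09374,1.076,0.01033,1.006
DSB,C,INDIRECT,2.2,0.03152,0.6538,0.002669,1.114
DSB,N,TOTAL,6.8,0.2043,1.023,0.01002,1.121
DSB,N,DIRECT,2.8,0.09184,1.103,0.01089,1.05
DSB,N,INDIRECT,2.2,0.03022,0.6392,0.002471,1.13
DSB,O,TOTAL,6.8,0.2122,1.077,0.01311,1.146
DSB,O,DIRECT,2.8,0.108,1.184,0.01773,1.088
DSB,O,INDIRECT,2.2,0.03304,0.6638,0.002959,1.085
DSB,Ne,TOTAL,6.8,0.1916,1.112,0.01261,1.204
DSB,Ne,DIRECT,2.8,0.09018,1.34,0.01838,1.263
DSB,Ne,INDIRECT,2.2,0.0308,0.5917,0.002172,1.081
DSB_CLUSTER,H,TOTAL,0.07,0.01532,2.396,NA,NA
DSB_CLUSTER,H,DIRECT,0.018,0.01152,2.844,NA,NA
DSB_CLUSTER,H,INDIRECT,0.004,0.002534,1.952,NA,NA
DSB_CLUSTER,He,TOTAL,0.07,0.01015,1.794,0.003817,3.255
DSB_CLUSTER,He,DIRECT,0.018,0.006072,1.762,NA,NA
DSB_CLUSTER,He,INDIRECT,0.004,0.00101,1.464,NA,NA
DSB_CLUSTER,Li,TOTAL,0.07,0.008907,2.004,0.004511,2.064
DSB_CLUSTER,Li,DIRECT,0.018,0.005925,2.183,0.004068,1.607
DSB_CLUSTER,Li,INDIRECT,0.004,0.0006276,1.35,NA,NA
DSB_CLUSTER,Be,TOTAL,0.07,0.007692,1.736,0.003448,2.088
DSB_CLUSTER,Be,DIRECT,0.018,0.00427,1.746,0.002058,2.09
DSB_CLUSTER,Be,INDIRECT,0.004,0.00048,1.242,0.001365,5.796
DSB_CLUSTER,B,TOTAL,0.07,0.007604,1.726,0.003789,1.991
DSB_CLUSTER,B,DIRECT,0.018,0.004394,1.817,0.002721,1.85
DSB_CLUSTER,B,INDIRECT,0.004,0.0003195,1.1,0.001242,37.32
DSB_CLUSTER,C,TOTAL,0.07,0.006858,1.498,0.002778,2.208
DSB_CLUSTER,C,DIRECT,0.018,0.003932,1.678,0.002187,2.14
DSB_CLUSTER,C,INDIRECT,0.004,0.0005724,1.265,0.001473,1.094
DSB_CLUSTER,N,TOTAL,0.07,0.00661,1.418,0.002577,2.194
DSB_CLUSTER,N,DIRECT,0.018,0.003585,1.519,0.00184,2.216
DSB_CLUSTER,N,INDIRECT,0.004,0.0004915,1.207,0.00144,0.9436
DSB_CLUSTER,O,TOTAL,0.07,0.007119,1.514,0.003193,2.095
DSB_CLUSTER,O,DIRECT,0.018,0.003711,1.533,0.002088,2.046
DSB_CLUSTER,O,INDIRECT,0.004,0.0005992,1.322,0.002002,1.108
DSB_CLUSTER,Ne,TOTAL,0.07,0.006894,1.418,0.002865,2.108
DSB_CLUSTER,Ne,DIRECT,0.018,0.003522,1.485,0.001971,2.097
DSB_CLUSTER,Ne,INDIRECT,0.004,0.001511,1.71,0.007381,1.29
DSB_SITE,H,TOTAL,6.8,0.1773,0.9314,NA,NA
DSB_SITE,H,DIRECT,2.8,0.06901,1.196,NA,NA
DSB_SITE,H,INDIRECT,2.2,0.035,0.5841,NA,NA
DSB_SITE,He,TOTAL,6.8,0.1471,1.038,0.006239,1.582
DSB_SITE,He,DIRECT,2.8,0.06555,1.023,0.003748,1.763
DSB_SITE,He,INDIRECT,2.2,0.02656,0.6415,0.002875,1.994
DSB_SITE,Li,TOTAL,6.8,0.1653,0.8782,0.004284,1.406
DSB_SITE,Li,DIRECT,2.8,0.06093,0.9556,0.003178,1.402
DSB_SITE,Li,INDIRECT,2.2,0.03349,0.6485,0.002736,1.109
DSB_SITE,Be,TOTAL,6.8,0.1425,0.95,0.005151,1.407
DSB_SITE,Be,DIRECT,2.8,0.06199,0.9224,0.003301,1.322
DSB_SITE,Be,INDIRECT,2.2,0.0341,0.7328,0.003678,1.136
DSB_SITE,B,TOTAL,6.8,0.1587,0.8714,0.004345,1.389
DSB_SITE,B,DIRECT,2.8,0.063,0.9255,0.003655,1.305
DSB_SITE,B,INDIRECT,2.2,0.03117,0.7196,0.003265,1.182
DSB_SITE,C,TOTAL,6.8,0.156,0.9214,0.005245,1.395
DSB_SITE,C,DIRECT,2.8,0.06191,0.9903,0.004525,1.369
DSB_SITE,C,INDIRECT,2.2,0.02946,0.6435,0.002585,1.166
DSB_SITE,N,TOTAL,6.8,0.1641,0.875,0.004607,1.391
DSB_SITE,N,DIRECT,2.8,0.06171,0.9649,0.004156,1.389
DSB_SITE,N,INDIRECT,2.2,0.02776,0.6216,0.00231,1.189
DSB_SITE,O,TOTAL,6.8,0.1749,0.8722,0.004987,1.347
DSB_SITE,O,DIRECT,2.8,0.0664,0.969,0.004754,1.341
DSB_SITE,O,INDIRECT,2.2,0.03004,0.6396,0.002652,1.136
DSB_SITE,Ne,TOTAL,6.8,0.1797,0.8657,0.004917,1.346
DSB_SITE,Ne,DIRECT,2.8,0.06408,1.023,0.0053,1.386
DSB_SITE,Ne,INDIRECT,2.2,0.02847,0.5684,0.002006,1.128
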