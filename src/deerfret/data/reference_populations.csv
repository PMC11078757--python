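condition,ligand,group,p26,p33,p39,p43,p45,p57,modulation_depth
apo,apo,ligand_only,0.3598,0.443,0.0296,0.0304,0.0801,0.0571,0.593
naloxone,naloxone,ligand_only,0.269,0.5013,0.0374,0.0426,0.0865,0.0632,0.426
TRV130,TRV130,ligand_only,0.3381,0.4356,0.057,0.063,0.0628,0.0435,0.52
PZM21,PZM21,ligand_only,0.2664,0.4669,0.0525,0.0575,0.0935,0.0632,0.643
MP,MP,ligand_only,0.3182,0.3821,0.0609,0.0691,0.0951,0.0746,0.442
buprenorphine,buprenorphine,ligand_only,0.3296,0.3984,0.0713,0.0787,0.0712,0.0508,0.573
morphine,morphine,ligand_only,0.2794,0.367,0.0888,0.1112,0.0919,0.0617,0.605
DAMGO,DAMGO,ligand_only,0.2845,0.3625,0.1155,0.1345,0.0665,0.0365,0.519
lofentanil,lofentanil,ligand_only,0.0509,0.0812,0.3436,0.3964,0.0793,0.0486,0.484
BU72,BU72,ligand_only,0.0251,0.045,0.3775,0.3925,0.0935,0.0664,0.473
apo+Gi,apo,Gi,0.2826,0.4399,0.0919,0.0481,0.0789,0.0586,0.379
naloxone+Gi,naloxone,Gi,0.3028,0.3749,0.0981,0.0619,0.0978,0.0645,0.518
TRV130+Gi,TRV130,Gi,0.1296,0.183,0.3369,0.2131,0.0783,0.0591,0.494
PZM21+Gi,PZM21,Gi,0.1092,0.2035,0.3268,0.1932,0.1,0.0673,0.391
MP+Gi,MP,Gi,0.1086,0.2108,0.3819,0.1981,0.0614,0.0392,0.621
buprenorphine+Gi,buprenorphine,Gi,0.1734,0.2098,0.2721,0.1779,0.1022,0.0646,0.591
morphine+Gi,morphine,Gi,0.1436,0.1729,0.3215,0.2285,0.0786,0.0549,0.58
DAMGO+Gi,DAMGO,Gi,0.0989,0.1206,0.4269,0.2231,0.0802,0.0503,0.578
lofentanil+Gi,lofentanil,Gi,0.0299,0.0379,0.4526,0.3274,0.0968,0.0554,0.535
BU72+Gi,BU72,Gi,0.0332,0.058,0.5138,0.2862,0.0646,0.0442,0.37
apo+barr1,apo,barr1,0.3159,0.4314,0.0547,0.0453,0.0854,0.0673,0.504
naloxone+barr1,naloxone,barr1,0.3118,0.417,0.0644,0.0556,0.0954,0.0558,0.457
TRV130+barr1,TRV130,barr1,0.2014,0.3326,0.1502,0.1498,0.1023,0.0637,0.481
PZM21+barr1,PZM21,barr1,0.2497,0.3637,0.1305,0.1495,0.061,0.0456,0.553
MP+barr1,MP,barr1,0.2412,0.3083,0.175,0.145,0.0826,0.0479,0.386
buprenorphine+barr1,buprenorphine,barr1,0.2548,0.3029,0.156,0.124,0.0974,0.0649,0.425
morphine+barr1,morphine,barr1,0.173,0.3328,0.2012,0.1788,0.0736,0.0406,0.363
DAMGO+barr1,DAMGO,barr1,0.1778,0.2813,0.2023,0.2177,0.0735,0.0474,0.487
lofentanil+barr1,lofentanil,barr1,0.0531,0.0702,0.3973,0.3627,0.0726,0.0441,0.412
BU72+barr1,BU72,barr1,0.026,0.0328,0.362,0.418,0.092,0.0692,0.482
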