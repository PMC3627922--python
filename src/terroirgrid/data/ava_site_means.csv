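zone,elevation,slope,insolation,awc,depth,ph,gdd,bedd,ffd,gsp
Yakima Valley,331,5.2,1031.2,0.169,165,7.62,1371,1204,162,89
Walla Walla Valley,315,10.6,1007.2,0.186,190,7.36,1487,1269,200,197
Columbia Valley,462,11.3,1022.1,0.163,141,7.28,1278,1110,163,125
Red Mountain,227,7.7,1016.7,0.161,186,7.40,1501,1341,176,89
Columbia Gorge,405,22.8,983.5,0.163,158,6.48,927,908,150,200
Horse Heaven Hills,323,6.6,1031.7,0.169,179,7.52,1435,1236,174,98
Wahluke Slope,251,3.0,1027.9,0.120,174,7.73,1512,1281,173,73
Rattlesnake Hills,433,11.5,1031.6,0.176,108,7.67,1214,1119,148,105
Snake River Valley,874,10.8,1111.9,0.153,120,7.59,1339,1135,139,136
Snipes Mountain,279,17.4,994.4,0.189,166,7.63,1447,1284,167,80
Lake Chelan,488,24.5,951.6,0.143,170,7.43,1198,1055,168,112
Naches Heights,542,10.6,1026.2,0.169,142,7.10,1061,937,119,125
Ancient Lakes,386,4.3,1026.3,0.143,157,7.55,1380,1210,167,83
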