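zone,drainage_ED,drainage_SED,drainage_WD,drainage_MWD,drainage_SPD,drainage_PD,drainage_VPD
Yakima Valley,1.9,5.6,78.4,0.6,13.2,0.3,
Walla Walla Valley,,3.9,86.8,4.9,4.2,0.2,
Columbia Valley,6.6,6.9,83.0,0.9,2.0,0.5,0.1
Red Mountain,0.6,14.9,84.5,,,,
Columbia Gorge,,0.2,96.7,,2.9,0.3,
Horse Heaven Hills,9.6,9.4,80.6,,0.3,0.1,
Wahluke Slope,34.7,33.7,31.5,,0.005,,
Rattlesnake Hills,,0.005,99.4,,0.6,,
Snake River Valley,1.8,4.6,86.7,0.8,4.7,1.2,0.1
Snipes Mountain,,0.3,99.2,,0.4,,
Lake Chelan,,0.9,90.0,9.1,,,
Naches Heights,,0.005,98.3,,1.7,,
Ancient Lakes,5.0,27.5,67.2,0.1,,0.2,
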