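{
 "GLCi": 2.263859748144,
 "G6P": 0.875068434761,
 "F6P": 0.213717573095,
 "FBP": 0.438075092875,
 "DHAP": 0.729750943323,
 "GAP": 0.029566221106,
 "BPG": 0.009814528266,
 "P3G": 0.903732110901,
 "P2G": 0.1209765546,
 "PEP": 0.706672437671,
 "PYR": 0.497271872073,
 "ACE": 0.039588001539,
 "G1P": 0.043860152018,
 "UDPG": 0.693532462414,
 "T6P": 1.002990541137,
 "TREc": 2.814089132638,
 "G3P": 0.14875300545,
 "GLYCO": 89.466688737315,
 "ATP": 3.986830827099,
 "ADP": 1.010430640046,
 "AMP": 0.115238532855,
 "NAD": 1.50029227098,
 "NADH": 0.05970772902,
 "PI": 10.013251778765,
 "TREv": 0.908345510676,
 "GLCec": 2.415898639423,
 "TREec": 0.29679284171,
 "VOL": 2.0
}
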