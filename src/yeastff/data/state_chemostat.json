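{
 "GLCi": 0.12,
 "G6P": 0.9,
 "F6P": 0.22,
 "FBP": 0.45,
 "DHAP": 0.74,
 "GAP": 0.03,
 "BPG": 0.01,
 "P3G": 0.9,
 "P2G": 0.12,
 "PEP": 0.7,
 "PYR": 0.5,
 "ACE": 0.04,
 "G1P": 0.045,
 "UDPG": 0.7,
 "T6P": 1.077716036138,
 "TREc": 3.0,
 "G3P": 0.15,
 "GLYCO": 100.0,
 "ATP": 4.0,
 "ADP": 1.0,
 "AMP": 0.1125,
 "NAD": 1.5,
 "NADH": 0.06,
 "PI": 10.0,
 "TREv": 1.0,
 "GLCec": 0.722484416741,
 "TREec": 0.3,
 "VOL": 2.0
}
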