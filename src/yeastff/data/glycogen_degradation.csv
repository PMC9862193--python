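time_s,flux_mM_per_s
0.0,0.01330998505
20.0,0.003802852872
60.0,0.002376783045
120.0,0.004278209481
200.0,0.01140855862
300.0,0.01330998505
400.0,0.01330998505
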