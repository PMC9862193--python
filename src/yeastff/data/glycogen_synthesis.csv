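time_s,flux_mM_per_s
0.0,0.004445473489
20.0,0.01778189396
60.0,0.02963648993
120.0,0.01778189396
200.0,0.006668210234
300.0,0.004445473489
400.0,0.004445473489
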