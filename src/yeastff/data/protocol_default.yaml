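dilution_per_h: 0.1
cs_chem_g_per_l: 37.487308
cycle_s: 400.0
feed_s: 20.0
multiplier: 20.0
outflow_end_s: 260.0
n_cycles: 20
residence_times: 5.0
biomass_gdw_per_l: 16.0
vacuole_fraction: 0.1
label_fraction: 0.99
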