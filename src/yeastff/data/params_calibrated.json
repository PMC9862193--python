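{
 "role": "estimated",
 "units": {
  "Keq": "1",
  "Ki": "mM",
  "Km": "mM",
  "Vmax": "mM/s"
 },
 "values": {
  "ADH.Km_ACE": 0.5,
  "ADH.Km_NADH": 0.03,
  "ADH.Vmax": 2.6325000000000003,
  "ADK.Keq": 0.45,
  "ADK.k": 10.0,
  "AGT1.Keq": 1.0,
  "AGT1.Ki_T6P": 50.0,
  "AGT1.Km_TREc": 0.3,
  "AGT1.Km_TREec": 10.0,
  "AGT1.Vmax": 0.0003622602931318155,
  "ATH1.Ki_T6P": 1.0,
  "ATH1.Km_TREv": 1.2,
  "ATH1.Vmax": 0.02285487639751553,
  "ATPASE.k": 0.04074363425925926,
  "ENO.Keq": 6.7,
  "ENO.Km_P2G": 0.04,
  "ENO.Km_PEP": 0.5,
  "ENO.Vmax": 3.8802019230769242,
  "FBA.Keq": 0.069,
  "FBA.Km_DHAP": 2.0,
  "FBA.Km_FBP": 0.3,
  "FBA.Km_GAP": 2.4,
  "FBA.Vmax": 1.2116206099929372,
  "G3PDH.Km_DHAP": 0.54,
  "G3PDH.Km_NADH": 0.023,
  "G3PDH.Vmax": 0.0957117117117117,
  "GAPDH.Keq": 0.05,
  "GAPDH.Km_BPG": 0.0098,
  "GAPDH.Km_GAP": 0.21,
  "GAPDH.Km_NAD": 0.09,
  "GAPDH.Km_NADH": 0.06,
  "GAPDH.Km_PI": 10.0,
  "GAPDH.Vmax": 8.484525613275613,
  "GLK.Ki_T6P": 0.0183,
  "GLK.Km_ATP": 0.9,
  "GLK.Km_GLC": 0.11,
  "GLK.Vmax": 15.75,
  "GLYD.Ksat_GLY": 1.0,
  "GLYD.v_chemostat": 0.0101,
  "GLYS.Ksat_UDPG": 0.1,
  "GLYS.v_chemostat": 0.011428571428571429,
  "GPM.Keq": 0.19,
  "GPM.Km_P2G": 0.3,
  "GPM.Km_P3G": 1.2,
  "GPM.Vmax": 2.680169389978213,
  "GPP.Km_G3P": 1.0,
  "GPP.Vmax": 0.3066666666666667,
  "HXT.GLCec_min": 0.45,
  "HXT.Keq": 1.0,
  "HXT.Ki": 10.0,
  "HXT.Km": 0.9,
  "HXT.Vmax": 1.7,
  "MITONADH.Km_NADH": 0.1,
  "MITONADH.Vmax": 0.39691358024691364,
  "NTH1.Km_TRE": 2.11,
  "NTH1.Vmax": 0.01703333333333333,
  "PDC.K05_PYR": 4.0,
  "PDC.Vmax": 11.62476851851852,
  "PDC.n": 2.0,
  "PFK.Ka_AMP": 0.05,
  "PFK.Ki_ATP": 1.0,
  "PFK.Km_ATP": 0.7,
  "PFK.Km_F6P": 0.25,
  "PFK.L0": 5.0,
  "PFK.Vmax": 1.9584343607114048,
  "PFK.n": 2.0,
  "PGI.Keq": 0.29,
  "PGI.Km_F6P": 0.3,
  "PGI.Km_G6P": 1.4,
  "PGI.Vmax": 4.221797688949114,
  "PGK.Keq": 3200.0,
  "PGK.Km_ADP": 0.2,
  "PGK.Km_ATP": 0.3,
  "PGK.Km_BPG": 0.003,
  "PGK.Km_P3G": 0.53,
  "PGK.Vmax": 1.3725059399021666,
  "PGM1.Keq": 17.0,
  "PGM1.Km_G1P": 0.05,
  "PGM1.Km_G6P": 0.67,
  "PGM1.Vmax": 0.31221887604160264,
  "PIBUF.PI_ref": 11.70578703703704,
  "PIBUF.k": 0.05,
  "PYK.K05_PEP": 2.0,
  "PYK.Ka_FBP": 0.3,
  "PYK.Km_ADP": 0.53,
  "PYK.Vmax": 1.0634633746355688,
  "PYK.n": 3.0,
  "SINKACE.Km": 0.5,
  "SINKACE.Vmax": 0.6593750000000006,
  "SINKG6P.Km": 2.0,
  "SINKG6P.Vmax": 0.06444444444444444,
  "SINKP3G.Km": 1.0,
  "SINKP3G.Vmax": 0.08444444444444445,
  "SINKPYR.Km": 1.0,
  "SINKPYR.Vmax": 0.6818181818181819,
  "SINKPYR.factor": 0.44,
  "TPI.Keq": 0.045,
  "TPI.Km_DHAP": 6.45,
  "TPI.Km_GAP": 5.25,
  "TPI.Vmax": 13.739697150072148,
  "TPS1.Km_G6P": 2.0,
  "TPS1.Km_UDPG": 0.5,
  "TPS1.Vmax": 0.08445546737213402,
  "TPS2.Km_T6P": 0.5,
  "TPS2.Vmax": 0.022382756486826246,
  "UGP.Keq": 300.0,
  "UGP.Ki_G1P": 0.1,
  "UGP.Km_ATP": 1.0,
  "UGP.Km_G1P": 0.08,
  "UGP.Km_UDPG": 0.35,
  "UGP.Vmax": 0.3123503989361702,
  "VACT.Keq": 1.0,
  "VACT.Km_TREc": 5.0,
  "VACT.Km_TREv": 5.0,
  "VACT.Vmax": 0.0225
 }
}
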