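{
 "HXT.Vmax": {
  "reference": 8.13,
  "estimated": 1.7,
  "units": "mM/s"
 },
 "HXT.Km": {
  "reference": 1.01,
  "estimated": 0.9,
  "units": "mM"
 },
 "GLK.Vmax": {
  "reference": 6.25,
  "estimated": 15.75,
  "units": "mM/s"
 },
 "GLK.Km_GLC": {
  "reference": 0.35,
  "estimated": 0.11,
  "units": "mM"
 },
 "GLK.Ki_T6P": {
  "reference": 0.0073,
  "estimated": 0.0183,
  "units": "mM"
 }
}
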