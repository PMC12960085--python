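{
 "ve_cubic": {
  "kind": "cubic",
  "predictor": "ve_peak",
  "coefficients": [
   -0.1918,
   0.01515,
   -0.0001075,
   3.927e-07
  ]
 },
 "age_linear": {
  "kind": "linear",
  "predictor": "age",
  "coefficients": [
   0.5916,
   0.009138
  ]
 },
 "height_expgrowth": {
  "kind": "expgrowth",
  "predictor": "height",
  "coefficients": [
   0.08766,
   0.01293
  ]
 },
 "weight_cubic": {
  "kind": "cubic",
  "predictor": "weight",
  "coefficients": [
   2.84,
   -0.1442,
   0.002706,
   -1.486e-05
  ]
 },
 "vo2peak_linear": {
  "kind": "linear",
  "predictor": "vo2peak",
  "coefficients": [
   0.196,
   0.1643
  ]
 },
 "hrmax_linear": {
  "kind": "linear",
  "predictor": "hr_max",
  "coefficients": [
   1.392,
   -0.002975
  ]
 }
}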