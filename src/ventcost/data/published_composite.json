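{
 "c0_list": [
  57.398416273464,
  5.6212655970623,
  38.4177594334086,
  21.2264109748025,
  25.042348428592
 ],
 "ve1": -0.000970005711277,
 "ve2": 1.7651237164e-05,
 "ve3": 8.2921e-08,
 "w1": -0.110606151444052,
 "w2": 0.001874750053414,
 "w3": -1.002e-05,
 "h_scale": -144.186859758223,
 "h_rate": 6.302e-05,
 "age1": -0.00053642470208,
 "vp1": 0.062213494704466,
 "hr1": 0.001880224895256,
 "provenance": "published"
}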