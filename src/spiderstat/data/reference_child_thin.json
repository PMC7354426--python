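{
 "kind": "thin",
 "rest_length_m": 0.6375,
 "terms": [
  {
   "a_N": 85.64881153483219,
   "b_per_pct": 0.014095658962097813,
   "c_rad": 0.019422464325820264
  },
  {
   "a_N": 153.31904250683445,
   "b_per_pct": 0.06200114147769204,
   "c_rad": -1.0084136010696712
  },
  {
   "a_N": 145.95778898869523,
   "b_per_pct": 0.06283185307179585,
   "c_rad": 2.0728955262390847
  }
 ],
 "r_squared": 0.9999929717484566,
 "provenance": {
  "note": "synthetic: 3-term sum-of-sines fit to a noiseless calibrated bench curve, not a physical measurement",
  "generator": {
   "saturation_n": 80.0,
   "scale_pct": 34.974851806336794,
   "toe_exponent": 1.1,
   "grid": [
    0.0,
    5.0,
    10.0,
    15.0,
    20.0,
    25.0,
    30.0,
    35.0,
    40.0,
    45.0,
    50.0,
    55.0,
    60.0,
    65.0,
    70.0,
    75.0,
    80.0,
    85.0,
    90.0,
    95.0,
    100.0
   ]
  },
  "fit_seed": 7
 }
}
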