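{
 "kind": "thick",
 "rest_length_m": 0.6175,
 "terms": [
  {
   "a_N": 167.15199703433083,
   "b_per_pct": 0.022162936958873506,
   "c_rad": -1.2014033056976086
  },
  {
   "a_N": 167.1519802411209,
   "b_per_pct": 0.003937110862114467,
   "c_rad": 2.6559803791165892
  },
  {
   "a_N": 77.96045661673413,
   "b_per_pct": 0.028820313377392055,
   "c_rad": 1.5014432883730193
  }
 ],
 "r_squared": 0.9999969245374661,
 "provenance": {
  "note": "synthetic: 3-term sum-of-sines fit to a noiseless calibrated bench curve, not a physical measurement",
  "generator": {
   "saturation_n": 150.0,
   "scale_pct": 120.49550850017874,
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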