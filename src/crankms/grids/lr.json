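{
 "family": "LR",
 "axes": {
  "C": [
   0.0001,
   0.000189,
   0.000356,
   0.000672,
   0.001269,
   0.002395,
   0.00452,
   0.008532,
   0.016103,
   0.030392,
   0.057362,
   0.108264,
   0.204336,
   0.385662,
   0.727895,
   1.373824,
   2.592944,
   4.893901,
   9.236709,
   17.433288,
   32.903446,
   62.101694,
   117.21023,
   221.221629,
   417.531894,
   788.046282,
   1487.352107,
   2807.216204,
   5298.316906,
   10000.0
  ],
  "class_weight": [
   null,
   "balanced"
  ],
  "fit_intercept": [
   true,
   false
  ]
 }
}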