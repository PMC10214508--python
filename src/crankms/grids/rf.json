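{
 "family": "RF",
 "axes": {
  "n_estimators": [
   100,
   200,
   400,
   600,
   800
  ],
  "max_depth": [
   null,
   4,
   8,
   16
  ],
  "max_features": [
   "sqrt",
   "log2",
   0.2
  ],
  "min_samples_split": [
   2,
   4
  ]
 }
}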