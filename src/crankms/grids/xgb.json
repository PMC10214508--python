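{
 "family": "XGB",
 "axes": {
  "n_estimators": [
   50,
   100,
   200,
   400,
   800
  ],
  "max_depth": [
   2,
   3,
   4,
   6
  ],
  "learning_rate": [
   0.05,
   0.1,
   0.3
  ],
  "subsample": [
   0.8,
   1.0
  ]
 }
}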