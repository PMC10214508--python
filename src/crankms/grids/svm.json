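{
 "family": "SVM",
 "axes": {
  "kernel": [
   "linear",
   "rbf"
  ],
  "C": [
   0.001,
   0.004642,
   0.021544,
   0.1,
   0.464159,
   2.154435,
   10.0,
   46.415888,
   215.443469,
   1000.0
  ],
  "gamma": [
   "scale",
   "auto",
   0.01,
   0.1,
   1.0,
   10.0
  ]
 }
}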