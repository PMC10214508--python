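{
 "family": "NN",
 "axes": {
  "hidden_layer_sizes": [
   [
    32
   ],
   [
    64
   ],
   [
    64,
    32
   ],
   [
    128,
    64
   ],
   [
    32,
    16
   ]
  ],
  "learning_rate_init": [
   0.01,
   0.001,
   0.0001
  ],
  "alpha": [
   0.0,
   0.0001,
   0.001,
   0.01
  ],
  "batch_size": [
   16,
   32
  ]
 }
}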