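{
 "format_version": 1,
 "proton": {
  "let": [
   1.0,
   2.0,
   3.0,
   5.0,
   7.0,
   10.0,
   15.0,
   20.0,
   25.0,
   30.0
  ],
  "nu": [
   0.024226,
   0.02359,
   0.021625,
   0.01771,
   0.015577,
   0.012784,
   0.010681,
   0.012853,
   0.020643,
   0.033952
  ],
  "sigma_nm": [
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0
  ]
 },
 "alpha": {
  "let": [
   1.0,
   2.0,
   3.0,
   5.0,
   7.0,
   10.0,
   15.0,
   20.0,
   25.0,
   30.0
  ],
  "nu": [
   0.028319,
   0.031023,
   0.036665,
   0.057336,
   0.095296,
   0.173917,
   0.399228,
   0.774961,
   1.336603,
   2.1184
  ],
  "sigma_nm": [
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0,
   15.0
  ]
 }
}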