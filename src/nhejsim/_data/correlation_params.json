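{
  "format_version": 1,
  "description": "Fitted correlation constants per ion species. a,b: misrepair fraction vs 70 nm cluster density (slope, intercept); c: constant residual fraction at 24 h; d,e: initial DSB yield per Gy vs LET_t (slope keV/um^-1, intercept); f,g,h: quadratic cluster density vs LET_t. Percent entries are asymptotic standard errors of the fits, stored as metadata only.",
  "proton": {
    "a": 0.1966, "b": 0.008, "c": 0.0736,
    "d": 1.149, "e": 24.10,
    "f": 4.879e-4, "g": 2.84e-3, "h": 5.13e-2,
    "stderr_percent": {"a": 0.4, "b": 3.4, "c": 0.2, "d": 1.0, "e": 0.6,
                       "f": 0.8, "g": 4.7, "h": 1.6}
  },
  "alpha": {
    "a": 0.1966, "b": 0.008, "c": 0.0736,
    "d": 1.02, "e": 20.2,
    "f": 3.25e-3, "g": 1.61e-3, "h": 5.51e-2,
    "stderr_percent": {"a": 0.6, "b": 3.4, "c": 0.2, "d": 2.5, "e": 1.3,
                       "f": 5.0, "g": 33.0, "h": 5.7}
  }
}
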