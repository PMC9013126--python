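{
  "intercept": -6.18,
  "coef_cT": -0.95,
  "coef_cN": 0.53,
  "coef_skewness": -3.01,
  "coef_entropy": 3.61,
  "sd_intercept": 3.0,
  "sd_cT": 0.36,
  "sd_cN": 0.35,
  "sd_skewness": 1.17,
  "sd_entropy": 1.68,
  "sigma_entropy_mm": 0.344,
  "sigma_skewness_mm": 0.485,
  "threshold": 0.267
}
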