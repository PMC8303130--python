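{
  "reference": "Remission",
  "horizon_years": 1.0,
  "states": {
    "Remission": {"mean": 0.85, "beta_alpha": 923, "beta_beta": 163},
    "Lsever": {"mean": 0.60, "beta_alpha": 182, "beta_beta": 122},
    "Msever": {"mean": 0.42, "beta_alpha": 54, "beta_beta": 75}
  }
}
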