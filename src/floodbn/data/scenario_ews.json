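{
  "label": "flood early-warning system (local Environment Agency)",
  "before": {"Msever": 0.055, "Lsever": 0.062},
  "after": {"Msever": 0.033, "Lsever": 0.038},
  "threshold": 20000
}
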