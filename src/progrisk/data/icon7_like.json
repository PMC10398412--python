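{
  "control_rates": [[0, 0.00134]],
  "relative_hazard": [[0, 0.6], [180, 0.85], [365, 1.0], [395, 1.4], [720, 1.0]],
  "censor_rate": 0.0003,
  "admin_cutoff_day": 1095,
  "discontinuation_day": 365
}
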