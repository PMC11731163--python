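{
  "task1": {
    "mean_a": 86.0,
    "mean_b": 94.0,
    "sd": 5.0
  },
  "task2": {
    "mean": 0.0,
    "sd_narrow": 3.0,
    "sd_broad": 12.0
  },
  "contrasts": [
    0.004,
    0.016,
    0.033,
    0.093,
    0.18,
    0.36,
    0.72
  ],
  "base_rates": [
    0.25,
    0.5,
    0.75
  ],
  "trials_per_block": 320,
  "exp1_sessions": 1,
  "exp2_sessions": 2
}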