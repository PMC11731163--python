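check_rate: 0.0125
counterbalance: true
experiment: 2
group_means:
  autistic:
    boundary_scale: 1.0
    gamble_sd: 5.0
    gamble_weight: 1.0
    lapse_rate: 0.02
    noise_exponent: 0.9
    noise_misestimate: 1.0
    noise_scale: 0.08
    prior_weight: 1.0
    sigma_floor: 2.0
  non-autistic:
    boundary_scale: 1.0
    gamble_sd: 5.0
    gamble_weight: 1.0
    lapse_rate: 0.02
    noise_exponent: 0.9
    noise_misestimate: 1.0
    noise_scale: 0.08
    prior_weight: 1.0
    sigma_floor: 2.0
n_per_group:
  autistic: 34
  non-autistic: 44
param_sds:
  boundary_scale: 0.1
  gamble_sd: 1.0
  gamble_weight: 0.1
  lapse_rate: 0.01
  noise_misestimate: 0.1
  noise_scale: 0.02
  prior_weight: 0.15
  sigma_floor: 0.3
seed: 0
trials_per_block: 320
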