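accuracy_threshold: 0.6
bin_centers:
- -14.0
- -12.0
- -10.0
- -8.0
- -6.0
- -4.0
- -2.0
- 0.0
- 2.0
- 4.0
- 6.0
- 8.0
- 10.0
- 12.0
- 14.0
c_error_max: 50.0
correction: loglinear
k_error_max: 35.0
k_max: 100.0
n_top_contrasts: 3
seed: 0
sigma_max: 100.0
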