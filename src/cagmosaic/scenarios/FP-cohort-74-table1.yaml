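# Full-penetrance blood cohort in "table 1" mode: the 40-50 CAG window
# (n=74), slopes 0.125 per CAG and 0.011 per year; noise_sd from the
# category's reported R^2, intercept anchoring the expected minimum.
kind: cohort
category: full_penetrance
n_samples: 74
cag_range: [40, 50]
age_range: [20, 90]
coeffs:
  intercept: -4.43
  beta_cag: 0.125
  beta_age: 0.011
  beta_interaction: 0.0
  noise_sd: 0.28
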