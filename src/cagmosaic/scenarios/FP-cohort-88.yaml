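# Full-penetrance blood cohort in "results text" mode: all >=40 CAG alleles
# (n=88, CAG 40-55), slopes 0.133 per CAG and 0.011 per year.  noise_sd is
# calibrated from the category's reported R^2 (~0.74) against the variance
# the covariates explain under uniform sampling; intercept anchors the
# expected cohort minimum near the published category minimum (~0.148).
kind: cohort
category: full_penetrance
n_samples: 88
cag_range: [40, 55]
age_range: [20, 90]
coeffs:
  intercept: -4.44
  beta_cag: 0.133
  beta_age: 0.011
  beta_interaction: 0.0
  noise_sd: 0.385
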