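# Normal-allele blood cohort: n=47, CAG uniform on 10-26.  Slopes are the
# published per-CAG and per-year effects for the normal category; noise_sd
# is a compromise between the value implied by the printed ratio range
# (which assumes uniform CAG coverage the real cohort does not have) and
# the value implied by the reported R^2.
kind: cohort
category: normal
n_samples: 47
cag_range: [10, 26]
age_range: [20, 90]
coeffs:
  intercept: 0.0025
  beta_cag: 0.001
  beta_age: -0.00002
  beta_interaction: 0.0
  noise_sd: 0.003
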