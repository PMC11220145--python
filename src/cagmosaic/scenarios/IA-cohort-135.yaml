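# Intermediate-allele blood cohort: n=135, CAG uniform on 27-35, age uniform
# on 20-90.  Slopes are the published per-CAG and per-year effects for this
# category; intercept and noise_sd are calibrated so the simulated ratio
# min-max at n=135 spans ~0.020-0.091 (the expected extreme of 135 normal
# deviates is ~2.47 sd).
kind: cohort
category: intermediate
n_samples: 135
cag_range: [27, 35]
age_range: [20, 90]
coeffs:
  intercept: -0.074
  beta_cag: 0.004
  beta_age: 0.0001
  beta_interaction: 0.0
  noise_sd: 0.0065
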