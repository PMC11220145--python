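# Reduced-penetrance blood cohort: n=37, CAG uniform on 36-39.  Slopes are
# the published per-CAG and per-year effects; intercept and noise_sd
# calibrated so the simulated ratio min-max at n=37 spans ~0.063-0.878.
kind: cohort
category: reduced_penetrance
n_samples: 37
cag_range: [36, 39]
age_range: [20, 90]
coeffs:
  intercept: -1.457
  beta_cag: 0.047
  beta_age: 0.003
  beta_interaction: 0.0
  noise_sd: 0.1055
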