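# Covariate-adjusted group comparison scenario: population-control (n=46)
# and symptomatic (n=78) intermediate-allele carriers drawn from the SAME
# generating model, mimicking the published negative finding (no group
# difference after adjusting for CAG and age).
kind: cohort
category: intermediate
groups:
  - group: control
    category: intermediate
    n_samples: 46
    cag_range: [27, 35]
    age_range: [20, 90]
    id_prefix: CT
    coeffs:
      intercept: -0.074
      beta_cag: 0.004
      beta_age: 0.0001
      beta_interaction: 0.0
      noise_sd: 0.0065
  - group: symptomatic
    category: intermediate
    n_samples: 78
    cag_range: [27, 35]
    age_range: [20, 90]
    id_prefix: SY
    coeffs:
      intercept: -0.074
      beta_cag: 0.004
      beta_age: 0.0001
      beta_interaction: 0.0
      noise_sd: 0.0065
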