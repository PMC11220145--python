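# Default PCR-stutter model, calibrated so the single-molecule assay's
# expected +1/inherited read ratio equals the benchmark value below for a
# 33 CAG template (see synthetic_data.calibrate_p_plus).
schema_version: 1
cycles: 30
p_minus: 0.01
p_plus: 0.0015381580287766657
length_scaling: 1.05
reference_cag: 33
calibration:
  target_plus1_ratio: 0.023
  template_cag: 33
  error_rate: 0.001
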