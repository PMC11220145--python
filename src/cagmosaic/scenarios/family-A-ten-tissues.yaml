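# Ten-tissue brain panel of a heterozygous 18/33 CAG carrier.
#
# Per-tissue targets are MEASURED per-offset expansion ratios (reads at
# inherited+i over reads at inherited length) as the assay reports them,
# i.e. including the PCR-stutter baseline.  Putamen and cerebellum values
# solve the four published constraints exactly (tissue totals 0.103 and
# 0.048; +1 and +2 putamen/cerebellum fold changes 2x and 5x).  The other
# eight tissues are SYNTHETIC interpolations following the qualitative
# striatum > cortex > brainstem/cerebellum gradient; no per-tissue numbers
# are published for them.
kind: tissue_panel
allele_short:
  cag: 18
allele_long:
  cag: 33
depth: 20000
n_templates: 200000
error_rate: 0.001
tissues:
  putamen:
    measured_ratios: {1: 0.0913333333, 2: 0.0116666667}
  caudate_nucleus:
    measured_ratios: {1: 0.0875, 2: 0.0105}
  substantia_nigra:
    measured_ratios: {1: 0.077, 2: 0.008}
  hippocampus:
    measured_ratios: {1: 0.073, 2: 0.007}
  frontal_lobe:
    measured_ratios: {1: 0.069, 2: 0.006}
  temporal_lobe:
    measured_ratios: {1: 0.065, 2: 0.005}
  occipital_lobe:
    measured_ratios: {1: 0.0605, 2: 0.0045}
  pons:
    measured_ratios: {1: 0.0545, 2: 0.0035}
  medulla:
    measured_ratios: {1: 0.050, 2: 0.003}
  cerebellum:
    measured_ratios: {1: 0.0456666667, 2: 0.0023333333}
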