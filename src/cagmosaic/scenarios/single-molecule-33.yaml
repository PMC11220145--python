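# Single-molecule PCR benchmark: one 33 CAG input molecule, no somatic
# mosaicism; the emitted read-length distribution reflects stutter alone.
kind: single_molecule
template:
  cag: 33
n_reads: 50000
error_rate: 0.001
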