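# Full pipeline on a simulated cohort at the motivating study's scale.
simulate:
  n_participants: 5415
  seed: 1
wqs:
  n_boot: 1000
  seed: 1
  stratify: true
rcs:
  metal: pb
  n_knots: 4
  reference_percentile: 25
output_dir: rvometals_out
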