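# Full default synthetic root-cutting experiment, analysed end to end.
seed: 42
output_dir: ojip_out
simulate: {}
jip:
  eps_flat: 0.05
stats:
  parameters: [fm, fv_over_fm, pi_abs]
  stratify: clock_time
pipeline:
  n_circles: 12
  control: 0.0
  format: svg
threshold:
  parameters: [fm, fv_over_fm, pi_abs]
  clock_time: 13
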