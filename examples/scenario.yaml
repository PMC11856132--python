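scenario:
  n_targets: 6
  n_frames: 200
  arena: [960, 540]
  base_speed: 4.0
  turn_probability: 0.02
  fn_rate: 0.02
  fp_rate: 0.1
  jitter_std: 0.5
  inter_id_similarity: 0.4
  occlusion_windows: [[1, 50, 95], [3, 80, 120], [5, 130, 170]]
  seed: 1
tracker:
  max_age: 30
  validation_max_speed: 110.0
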