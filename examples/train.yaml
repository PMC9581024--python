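train:
  model_size: 100
  epochs: 10
  batch_size: 32
  learning_rate: 0.0004
  verts_learning_rate: 0.002
  seed: 1
schedule:
  sigma_start: 5.0
  sigma_floor: 1.2
  epochs: 10
noise:
  scatter_sigma: 0.0
  p_missing: 0.0
  spawn_rate: 0.0
  max_spawn: 1
data:
  model: two_cylinder
  n_base: 500
  augment_factor: 4
  size: 64
network:
  base_channels: 8
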