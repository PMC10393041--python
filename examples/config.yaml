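workdir: runs/demo
seed: 0

cohort:
  n_t1dm: 5
  n_t2dm: 15
  length_range: [200, 400]
  resolution_minutes: 15
  volatility_t1dm: 2.0
  volatility_t2dm: 4.0
  meal_spike_rate: 1.5
  seed: 1

alignment_method: ssr
horizon_minutes: 15
resolution_minutes: 15
test_points: 144
stride: 1

model:
  window: 8
  k: 5
  gcn_hidden: 64
  conv_channels: 32
  conv_kernel: 3
  gru_hidden: 64
  dropout_g: 0.2
  dropout_co: 0.2
  dropout_o: 0.2
  candidate_activation: sigmoid

train:
  epochs: 50
  learning_rate: 0.001
  batch_size: 16
  seed: 0
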