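# Small configuration for a quick smoke run (minutes, not converged).
model:
  num_centers: 64
  k: 8
train:
  max_epochs: 4
  learning_rate: 0.003
  points_supervised: 256
  augment: false
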