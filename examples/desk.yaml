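# Desk-scale end-to-end run on the synthetic template benchmark.
seed: 1
data:
  source: synthetic
  heldout_fraction: 0.1
model:
  n_layers: 2
  d_model: 128
  n_heads: 4
  d_ff: 256
  max_len: 64
  dropout: 0.0
train:
  batch_tokens: 1200
  max_steps: 3500
  checkpoint_interval: 100
  warmup_steps: 200
  lr_scale: 0.5
  averaging_window: 12
  label_smoothing: 0.1
predict:
  n: 10
  beam_width: 10
  max_len: 60
evaluate:
  ns: [1, 3, 5, 10]
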