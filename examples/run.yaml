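# Full synthetic study: 10+10 subjects, ~100 cycles each, grouped 10-fold CV.
# Run with:  cardiocycle run --config examples/run.yaml --both-centers
seed: 1
mode: cv
k: 10
center_kind: median
n_inputs: 3
peak_policy: annotations_first
n_subjects_per_class: 10
cycles_per_subject: 100
output_dir: runs/seed1-median
preprocess:
  target_fs: 256.0
  bandpass_low: 0.5
  bandpass_high: 40.0
  filter_order: 4
  edge_trim_fraction: 0.01
  normalization: max_abs
segmentation:
  lambda_pre: 0.4
  theta_post: 0.6
  fs: 256.0
mlp:
  hidden_neurons: 5
  learning_rate: 0.01
  max_epochs: 1000
  tolerance: 0.0001
  activation: relu
  optimizer: adam
  seed: 1
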