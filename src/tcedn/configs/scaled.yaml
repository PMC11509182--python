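# Scaled-down study configuration for the synthetic eye-region corpus.
#
# Half-width backbone on grayscale 32 x 90 clips (48 frames -> 16 by
# non-overlapping aggregation).  The learning rate is raised to 1e-3 for this
# short-horizon study (<= 30 epochs on 64 training clips); the schedule's
# geometric shape is unchanged.
input:
  channels: 1
  frame_height: 32
  frame_width: 90
  frames_per_clip: 48

aggregation:
  window_mode: nonoverlap
  alpha: 0.05
  beta: 0.05
  gamma: 0.90
  phi_mode: identity

stdwm:
  steps: [1]
  fuse_mode: single
  init_wv: 1.0
  init_wd: 0.1

backbone:
  stage_channels: [4, 8, 16, 32]
  blocks_per_stage: 2
  convs_per_block: 2
  conv_kernel: [3, 3, 3]
  temporal_stride_stages: [2, 3]
  convlstm_hidden: 32
  convlstm_kernel: [3, 3]
  head_channels: [16, 8]
  output_scale: 63.0

train:
  learning_rate: 1.0e-3
  decay_factor: 0.8
  decay_every: 30
  max_epochs: 30
  batch_size: 4
  seed: 0
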