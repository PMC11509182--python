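# Reference severity-regression configuration.
#
# Eye-strip input (270 wide x 80 high, RGB), 48 sampled frames compressed to
# 16 by non-overlapping three-frame attention aggregation.  The backbone uses
# 16 3x3x3 convolution layers (4 stages x 2 residual blocks x 2 convs) with
# stage widths calibrated so the whole model stays inside the lightweight
# budget (<= 5.08 M parameters, <= 2.85 GFLOPs at this input).
input:
  channels: 3
  frame_height: 80
  frame_width: 270
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
  stage_channels: [8, 16, 32, 64]
  blocks_per_stage: 2
  convs_per_block: 2
  conv_kernel: [3, 3, 3]
  temporal_stride_stages: [2, 3]
  convlstm_hidden: 64
  convlstm_kernel: [3, 3]
  head_channels: [32, 16]
  output_scale: 63.0

train:
  learning_rate: 2.5e-5
  decay_factor: 0.8
  decay_every: 30
  max_epochs: 120
  batch_size: 4
  seed: 0
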