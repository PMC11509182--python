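# Methods

## Problem and model

The package regresses a BDI-II depression-severity score (0–63) from a short
clip of pre-cropped eye-region video. The network is deliberately small —
the design goal is competitive accuracy at a parameter and FLOP budget far
below deep face-analysis backbones — and is trained end to end from raw
pixels, with no pre-training.

The pipeline is: attention-weighted frame aggregation (AWAM) → temporal-
difference fusion (STDWM) → residual 3-D CNN → peephole ConvLSTM →
2-D convolutional regression head. Canonical array layout throughout is
`(batch, channel, time, height, width)`.

### Frame aggregation

For reference frame `X_i` and neighbour `X_j`, the weight map is
`Norm(φ(X_j) ⊙ φ(X_i) / d)` and the aggregated frame is
`α·WF(X_{i−1},X_i) + γ·X_i + β·WF(X_{i+1},X_i)` with `α+β+γ = 1`. Choices
made where the operation is under-determined:

* **Norm** is max-absolute-value normalization per weight map: divide by the
  map's largest absolute entry; an all-zero map stays zero, a constant
  positive map becomes all ones. This yields element-wise multipliable
  weights in [−1, 1] — the property that motivates using a plain
  normalization rather than a softmax, which would force the weights to sum
  to one across pixels.
* **φ** defaults to the identity, making the module deterministic and
  parameter-free; an optional trainable per-channel pointwise map
  (`scale_c·x + shift_c`, identity-initialized) is available behind
  `phi_mode: learnable-pointwise`.
* **d** defaults to the number of pixels per channel (H·W), playing the role
  of the √d stabilizer in scaled dot-product attention.
* **Window modes.** Stride-1 sliding windows map T → T−2 (66 → 64 frames);
  non-overlapping triples with the centre frame as reference map T → T/3
  (48 → 16). These are the only two layouts that reconcile the documented
  frame-count pairs, and both are implemented; windows are fixed at three
  frames. Defaults α = β = 0.05, γ = 0.9 (neighbour weights kept in the
  0.05–0.1 range to limit aggregation noise).

### Temporal-difference fusion

`D_t = |V_t − V_{t−s}|` with zero padding at the clip start: for `t < s` the
output is `|V_t|` exactly, accepting that the first `s` frames contribute
raw magnitude rather than motion. Low orders (s = 1 default; 1–3 supported)
capture short-range expression changes. Multi-step "fusion" averages the
difference maps of all configured orders before a single weighted fusion —
this keeps the parameter count independent of the number of steps.

The fusion weights `W_v, W_d` are one trainable map each of the per-clip
feature shape `(C, T, H, W)`, shared across the batch (per-sample weights
would not be learnable parameters). Initialization `W_v ≡ 1`, `W_d ≡ 0.1`
starts the module near the identity so early training is stable while
motion features enter gradually. No regularization is applied to the maps.

STDWM operates on the aggregated pixel-level frames (C = image channels),
not between backbone layers.

### Backbone and head

The reference 3-D CNN has 16 convolution layers: 4 stages × 2 residual
blocks × 2 convolutions, kernel 3×3×3, batch-norm + ReLU, stride-2 spatial
downsampling on each stage's first convolution and stride-2 temporal
downsampling in the last two stages. Skip paths use 1×1×1 projections where
channels or strides change (these projections are not counted in the 16).
Stage widths in the shipped reference configuration are (8, 16, 32, 64) —
see "Calibration" below.

The ConvLSTM follows the peephole formulation exactly: input and forget
gates see `W_c• ∘ C_{t−1}`, the output gate sees `W_co ∘ C_t`, all as
Hadamard products with full state-shaped peephole maps. One layer, 64 hidden
channels, 3×3 gate convolutions, zero-initialized peepholes, forget-gate
bias 1. Only the final hidden state `H_T` feeds the head (one score per
clip).

The head is two 3×3 2-D convolutions (with batch norm), global average
pooling, and one linear unit whose output is multiplied by `output_scale`
(default 63, the BDI-II range). The scaling keeps the last layer's weights
O(1) regardless of the label scale; its bias initializes to 0.5 so training
starts from a mid-scale prediction (~31.5).

An ablation switch replaces the ConvLSTM with a fully connected peephole
LSTM on flattened features — implemented as a 1×1-kernel ConvLSTM on a
`(B, C·H·W, T, 1, 1)` block, which is algebraically the same thing — to
quantify what preserving spatial structure buys.

## Numerics

The package ships its own reverse-mode autodiff over numpy (`tcedn.nn`):
a dynamic tape with broadcast-aware arithmetic, im2col-based 3-D
convolution (patch matrices are recomputed in the backward pass rather than
stored — memory traffic, not FLOPs, dominates at these sizes), composite
batch normalization (momentum 0.1, identity affine init, eps 1e-5), and a
max-abs normalization primitive whose gradient includes the path through the
maximizing element. Parameters are float32; gradient-check tests run the
same code in float64. Convolutions use Kaiming fan-in initialization, linear
layers uniform ±1/√fan_in, biases zero. All randomness flows from explicit
`numpy` generators seeded from the configuration.

Degenerate inputs: an all-zero attention map normalizes to zero weights; a
difference order `s ≥ T` warns and returns `|V|`; non-finite inputs are
rejected at module boundaries; a non-finite training loss aborts with a
diagnostic.

## Complexity accounting

`count_params` / `count_flops` walk the configuration analytically.
Parameters count every trainable element. FLOPs use the
one-multiply-accumulate-equals-one-FLOP convention common for lightweight
video models (the 2×MAC figure is also reported); pointwise work (frame
aggregation, difference/fusion, batch norm, gate nonlinearities, residual
additions) is tallied in a separate bucket and included in the total.

**Calibration.** The published budget for the full model is ≤ 5.08 M
parameters and ≤ 2.85 GFLOPs, but the stage widths behind those figures are
not recoverable. At the 80 × 270 eye-strip input with 16 aggregated frames,
widths (16, 32, 64, 128) exceed the FLOP budget under any stride schedule
consistent with per-stage downsampling, so the reference configuration uses
(8, 16, 32, 64), giving 2.93 M parameters and 1.57 GFLOPs — comfortably
inside both bounds, which are upper limits rather than targets. The
reference input assumes the 48-frame / non-overlapping-aggregation protocol
(T = 16 after compression); the fusion weight maps scale linearly in T, so
the 66 → 64 sliding protocol would enlarge them fourfold.

## Training and evaluation protocol

Adam (β = 0.9/0.999), MSE loss, batch size 4, learning rate
`lr0 · 0.8^⌊epoch/30⌋`, up to 120 epochs at full scale, lr0 = 2.5e-5.
Splits are declared in the dataset manifest (default 70/15/15 with half-up
rounded counts); the best-validation-RMSE parameter snapshot is kept
alongside the final state. No early stopping. Metrics: MAE, RMSE (population
forms), per-clip absolute-error curves sorted by error and by true score,
fraction of clips under fixed error thresholds, and a 4×4 severity-band
confusion table. Band boundaries are inclusive integers (minimal 0–13, mild
14–19, moderate 20–28, severe 29–63); non-integer scores round half-up
before banding, since the instrument only produces integer totals.

Robustness stress tests perturb the raw clips before aggregation: rotation
by 30/60/90° about the frame centre (bilinear, zero fill), additive Gaussian
noise (σ = 0.05 default), additive uniform noise (±0.05), and one zeroed
axis-aligned rectangle per clip with side 10–30 % of the frame side — the
unprinted noise and mask parameters are package defaults, seeded and
configurable.

## Synthetic data

The generator renders a smooth skin-toned strip with two dark elliptical
eyes and brow bands, animated with seeded blink events (3-frame eyelid
closures at evenly spaced, jittered slots), a static severity-proportional
brow lowering, global sub-pixel jitter (smoothed random walk), and optional
Gaussian pixel noise. Severity modulates motion monotonically and in the
clinically motivated direction — higher severity means fewer blinks
(8 → 2 events per 48-frame clip) and smaller jitter (RMS 0.6 px scaled down
to 25 %). Clips that differ only in severity share all random draws, so the
motion statistic is strictly monotone at every seed, not merely on average.
Default geometry is 32 × 90 (grayscale), aspect-matching the 270 × 80 crop
while keeping CPU tests fast; the full geometry is configurable.

What the generator does *not* emulate: photorealistic appearance, identity
variation, expression semantics, illumination or pose changes, or any
clinically validated severity signal. Passing recovery tests therefore shows
that the architecture and training loop can extract a planted monotone
motion signal at desk scale — not that the model measures depression.

## Scaled-down study

The end-to-end check trains the half-width configuration (widths 4–32,
ConvLSTM hidden 32, grayscale 32 × 90 input, 48 → 16 frame aggregation;
~0.30 M parameters) on 64 synthetic training clips with 16 validation and 16
held-out clips, for at most 30 epochs. The published learning rate 2.5e-5
belongs to the full-scale regime (120 epochs, three-digit video counts); at
this horizon it cannot move the parameters appreciably, so the scaled study
uses Adam at 1e-3 with the same schedule shape — fixed in the shipped
`scaled` configuration. Success criteria: held-out MAE below the
predict-the-training-mean baseline and Spearman rank correlation ≥ 0.7
between predicted and true severities, plus the qualitative robustness
ordering (Gaussian noise degrades metrics more than a static occlusion,
because differential motion features cancel static content). The study runs
in about two minutes on one CPU.

## Known limitations

* The autodiff engine implements exactly the operator set this model needs;
  it is not a general framework (no mixed precision, no graph reuse).
* Batch-norm statistics with batch size 4 are noisy; evaluation always uses
  running estimates.
* The reference configuration is a calibrated representative of the
  published budget, not a reconstruction of the original layout.
* Synthetic clips are far easier than interview video; absolute error values
  on them say nothing about clinical performance.
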