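# tcedn

Lightweight video regression of depression severity from eye-region clips.

Automatic depression assessment from recorded interviews regresses a clinical
severity score — the Beck Depression Inventory-II (BDI-II, 0–63) — directly
from facial video. `tcedn` implements a compact end-to-end network for this
task, built for the pre-cropped eye strip (270 × 80) rather than the full
face, together with its training protocol, evaluation metrics, robustness
stress tests, complexity accounting, and a synthetic eye-region clip
generator so the whole pipeline is testable without access-restricted
interview corpora.

## The model

Four pieces, applied in order to a clip of `T` sampled frames:

1. **Attention-weighted aggregation (AWAM).** Each reference frame `X_i` is
   blended with its neighbours through pixel-wise attention weights

   `WF(X_j, X_i) = Norm(φ(X_j) ⊙ φ(X_i) / d) ⊙ X_i`

   `AF(X_i) = α·WF(X_{i−1}, X_i) + γ·X_i + β·WF(X_{i+1}, X_i)`, α+β+γ = 1.

   `Norm` is max-absolute-value normalization, so the weight map lies in
   [−1, 1] and can multiply the frame element-wise. Sliding windows compress
   66 frames to 64; non-overlapping triples compress 48 frames to 16.

2. **Self-learning time-difference weighting (STDWM).** Motion is encoded by
   s-th order absolute temporal differences `D_t = |V_t − V_{t−s}|` (zero
   padding at the clip start) and fused with the raw features through two
   trainable element-wise weight maps: `R = V ⊙ W_v + D ⊙ W_d`.

3. **Residual 3D-CNN + peephole ConvLSTM.** Sixteen 3×3×3 convolution layers
   in four residual stages encode the fused clip; a single convolutional
   LSTM with peephole connections (`i_t, f_t, o_t` gates with Hadamard
   cell-state terms) rolls over the remaining time steps.

4. **Regression head.** Two 2-D convolutions, global average pooling, and one
   linear unit map the final hidden state `H_T` to a severity score.

Training follows the published recipe: Adam on an MSE loss, batch size 4,
learning rate 2.5e-5 decayed by 0.8 every 30 epochs. Metrics are MAE and
RMSE; scores band into minimal (0–13), mild (14–19), moderate (20–28) and
severe (29–63).

There is no deep-learning framework dependency: the package carries its own
small reverse-mode autodiff engine over numpy (`tcedn.nn`) with exactly the
operations this architecture needs.

## Worked example

```python
import numpy as np
from tcedn import TCEDNModel

model = TCEDNModel.from_synthetic(n=96, seed=1)   # scaled config: 32x90 clips
res = model.fit()                                  # ~2 min on one CPU
print(res.summary())
report = res.evaluate("test")
print(f"test MAE {report.mae:.2f}, RMSE {report.rmse:.2f}")
```

prints (numbers from this exact seed):

```
TCEDN severity regression results
============================================
clips (train/val/test)   67/14/15
input (C, T, H, W)       (1, 16, 32, 90)
trainable parameters     302,877 (0.303 M)
forward cost             0.054 GFLOPs (MAC convention)
epochs run               30
best validation epoch    29
final learning rate      0.001
final train MAE / RMSE   3.695 / 4.713
best val MAE / RMSE      1.526 / 1.955
test MAE 1.91, RMSE 2.27
```

A test MAE near 2 BDI-II points against a label spread of ~18 means the
model recovered the severity signal the generator planted in the blink rate
and micro-motion amplitude. `res.robustness("test")` evaluates the same
model under rotations, additive noise and occlusion; on synthetic data, as
on real video, Gaussian noise hurts most and a static occluding rectangle
least, because the motion encoding is differential.

The command-line interface mirrors the library: `tcedn synth`, `tcedn
aggregate`, `tcedn train`, `tcedn eval`, `tcedn perturb`, `tcedn ablate`,
`tcedn complexity`.

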