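"""Self-learning time-difference weighting (STDWM).

Facial motion is encoded with s-th order absolute temporal differences

    D_t = | V_t - V_{t-s} |

computed over the time axis of a (B, C, T, H, W) feature block, with zero
padding at the clip start (so D_t = |V_t| for t < s; output depth equals
input depth).  Low orders (s = 1, 2, 3) capture short-range expression
changes; larger strides compare distant frames and mostly add noise.

The motion block is fused back with the raw features by the self-learning
weight fusion (SWFM): two trainable weight maps with the per-clip feature
shape, applied element-wise and broadcast over the batch,

    R = V * W_v + D * W_d.

``W_v`` initializes to 1 and ``W_d`` to 0.1, so the module starts near the
identity and motion features enter gradually during training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Module, Parameter, Tensor

__all__ = ["DiffConfig", "SWFMWeights", "time_difference", "swfm_fuse",
           "stdwm_forward", "STDWM"]

TIME_AXIS = 2  # canonical layout (batch, channel, time, height, width)


@dataclass
class DiffConfig:
    """Difference orders and fusion mode for the motion encoder."""

    steps: tuple = (1,)
    fuse_mode: str = "single"      # {"single", "mean-of-steps"}

    def __post_init__(self):
        self.steps = tuple(int(s) for s in self.steps)
        if len(self.steps) == 0:
            raise ValueError("steps must be a non-empty list of difference orders")
        if any(s < 1 for s in self.steps):
            raise ValueError("difference orders must be positive integers")
        if self.fuse_mode not in ("single", "mean-of-steps"):
            raise ValueError(f"unknown fuse_mode {self.fuse_mode!r}")
        if self.fuse_mode == "single" and len(self.steps) != 1:
            raise ValueError("fuse_mode='single' takes exactly one difference order")


def _wrap(x):
    if isinstance(x, Tensor):
        return x, True
    arr = np.asarray(x, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in feature block")
    return Tensor(arr), False


def time_difference(V, s: int):
    """Absolute s-th order temporal difference of a (B, C, T, H, W) block."""
    if s < 1:
        raise ValueError("difference order s must be >= 1")
    t, was_tensor = _wrap(V)
    if t.ndim != 5:
        raise ValueError("expected a 5-axis (B, C, T, H, W) block")
    T = t.shape[TIME_AXIS]
    if s >= T:
        warnings.warn(
            f"difference order s={s} >= clip depth T={T}: the whole output "
            "is |V| (zero-padded reference)",
            stacklevel=2,
        )
    shifted = t.pad_axis(TIME_AXIS, s, 0).narrow(TIME_AXIS, 0, T)
    out = (t - shifted).abs()
    return out if was_tensor else out.data


class SWFMWeights(Module):
    """The two learnable fusion weight maps, shaped like one clip's features."""

    def __init__(self, feature_shape: tuple, init_wv: float = 1.0,
                 init_wd: float = 0.1):
        super().__init__()
        C, T, H, W = feature_shape
        self.Wv = Parameter(np.full((1, C, T, H, W), init_wv))
        self.Wd = Parameter(np.full((1, C, T, H, W), init_wd))

    @property
    def feature_shape(self) -> tuple:
        return self.Wv.shape[1:]


def swfm_fuse(V, D, w: SWFMWeights):
    """Element-wise fusion R = V * W_v + D * W_d, broadcast over batch."""
    tv, wt_v = _wrap(V)
    td, wt_d = _wrap(D)
    if tv.shape != td.shape:
        raise ValueError(f"feature/motion shape mismatch: {tv.shape} vs {td.shape}")
    if tuple(tv.shape[1:]) != tuple(w.feature_shape):
        raise ValueError(
            f"weight maps {tuple(w.feature_shape)} do not match features "
            f"{tuple(tv.shape[1:])}"
        )
    out = tv * w.Wv + td * w.Wd
    return out if (wt_v or wt_d) else out.data


def stdwm_forward(V, cfg: DiffConfig, w: SWFMWeights):
    """Full module: difference encoding (one or averaged orders) + fusion."""
    t, was_tensor = _wrap(V)
    diffs = [time_difference(t, s) for s in cfg.steps]
    if cfg.fuse_mode == "single":
        D = diffs[0]
    else:
        acc = diffs[0]
        for d in diffs[1:]:
            acc = acc + d
        D = acc * (1.0 / len(diffs))
    out = swfm_fuse(t, D, w)
    return out if was_tensor else out.data


class STDWM(Module):
    """Module wrapper holding the fusion weights for a fixed feature shape."""

    def __init__(self, feature_shape: tuple, cfg: DiffConfig | None = None,
                 init_wv: float = 1.0, init_wd: float = 0.1):
        super().__init__()
        self.cfg = cfg or DiffConfig()
        self.weights = SWFMWeights(feature_shape, init_wv=init_wv, init_wd=init_wd)

    def forward(self, V):
        return stdwm_forward(V, self.cfg, self.weights)
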