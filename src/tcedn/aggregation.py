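"""Attention-weighted frame aggregation (AWAM).

A clip is compressed by replacing each reference frame with a weighted blend
of itself and its two temporal neighbours.  The neighbour contribution is
gated by a pixel-wise cross-attention weight map

    WF(Xj, Xi) = Norm(phi(Xj) * phi(Xi) / d) * Xi

where ``*`` is the element-wise (Hadamard) product, ``phi`` an optional
per-channel linear map, ``d`` a scaling factor stabilizing the product, and
``Norm`` a max-absolute-value normalization that keeps the weight map in
[-1, 1] so it can multiply the reference frame directly (a softmax would not
produce element-wise multipliable weights).  The aggregated frame is

    AF(Xi) = alpha * WF(X_{i-1}, Xi) + gamma * Xi + beta * WF(X_{i+1}, Xi)

with alpha + beta + gamma = 1.  Two window layouts are supported:

* ``sliding``     — stride-1 windows over interior frames: T -> T - 2
                    (66 sampled frames -> 64 aggregated frames);
* ``nonoverlap``  — consecutive disjoint triples, centre frame as reference:
                    T -> T / 3 (48 sampled frames -> 16 aggregated frames).

Functions accept either numpy arrays or autodiff :class:`~tcedn.nn.Tensor`
inputs and return the same kind; with the default identity ``phi`` the
operation is parameter-free and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Module, Parameter, Tensor, maxabs_normalize

__all__ = [
    "FrameSequence",
    "AggregationConfig",
    "LearnablePhi",
    "phi_map",
    "weight_frame",
    "aggregate_window",
    "aggregate_video",
]


@dataclass
class FrameSequence:
    """Ordered frames of one clip, shaped (T, C, H, W)."""

    frames: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4:
            raise ValueError("frames must be a (T, C, H, W) array")
        if self.frames.shape[0] < 1:
            raise ValueError("a clip needs at least one frame")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class AggregationConfig:
    """Weights and modes of the three-frame attention aggregation.

    ``alpha`` / ``beta`` weight the preceding / following neighbour, ``gamma``
    the reference frame; the three must sum to 1.  ``d`` defaults to the
    number of pixels per channel (H * W), mirroring the sqrt(d_k) stabilizer
    of scaled dot-product attention.
    """

    alpha: float = 0.05
    beta: float = 0.05
    gamma: float = 0.90
    d: float | None = None
    phi_mode: str = "identity"        # {"identity", "learnable-pointwise"}
    norm_mode: str = "max-abs"
    window_mode: str = "sliding"      # {"sliding", "nonoverlap"}

    def __post_init__(self):
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-6:
            raise ValueError("alpha + beta + gamma must equal 1")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("aggregation weights must be non-negative")
        if self.d is not None and self.d <= 0:
            raise ValueError("scaling factor d must be positive")
        if self.phi_mode not in ("identity", "learnable-pointwise"):
            raise ValueError(f"unknown phi_mode {self.phi_mode!r}")
        if self.norm_mode != "max-abs":
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")
        if self.window_mode not in ("sliding", "nonoverlap"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")

    def scale_for(self, frame_shape: tuple) -> float:
        if self.d is not None:
            return float(self.d)
        return float(frame_shape[-1] * frame_shape[-2])


class LearnablePhi(Module):
    """Trainable per-channel pointwise map phi(x) = scale_c * x + shift_c.

    Initialized to the identity so enabling it does not change the module's
    output until training moves the parameters.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.scale = Parameter(np.ones(channels))
        self.shift = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        C = self.scale.shape[0]
        if x.ndim == 3:           # (C, H, W)
            sh = (C, 1, 1)
        elif x.ndim == 4:         # (T, C, H, W)
            sh = (1, C, 1, 1)
        else:
            raise ValueError("phi expects a (C,H,W) frame or (T,C,H,W) clip")
        return x * self.scale.reshape(sh) + self.shift.reshape(sh)


def _wrap(x):
    if isinstance(x, Tensor):
        return x, True
    arr = np.asarray(x, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in input frame")
    return Tensor(arr), False


def phi_map(frame, cfg: AggregationConfig, phi: LearnablePhi | None = None):
    """Apply the attention-space mapping ``phi`` to one (C, H, W) frame."""
    t, was_tensor = _wrap(frame)
    if cfg.phi_mode == "identity":
        out = t
    else:
        if phi is None:
            raise ValueError("learnable-pointwise phi_mode requires a LearnablePhi")
        out = phi(t)
    return out if was_tensor else out.data


def _weight_frame_t(Xj: Tensor, Xi: Tensor, cfg: AggregationConfig,
                    phi: LearnablePhi | None, axes: tuple) -> Tensor:
    d = cfg.scale_for(Xi.shape)
    pj = Xj if cfg.phi_mode == "identity" else phi(Xj)
    pi = Xi if cfg.phi_mode == "identity" else phi(Xi)
    w = maxabs_normalize(pj * pi * (1.0 / d), axes=axes)
    return w * Xi


def weight_frame(Xj, Xi, cfg: AggregationConfig | None = None,
                 phi: LearnablePhi | None = None):
    """Attention-weighted frame WF(Xj, Xi) for two (C, H, W) frames."""
    cfg = cfg or AggregationConfig()
    tj, wt_j = _wrap(Xj)
    ti, wt_i = _wrap(Xi)
    if tj.shape != ti.shape:
        raise ValueError(f"frame shape mismatch: {tj.shape} vs {ti.shape}")
    out = _weight_frame_t(tj, ti, cfg, phi, axes=tuple(range(tj.ndim)))
    return out if (wt_j or wt_i) else out.data


def aggregate_window(Xprev, Xi, Xnext, cfg: AggregationConfig | None = None,
                     phi: LearnablePhi | None = None):
    """Aggregate one three-frame window around reference frame ``Xi``."""
    cfg = cfg or AggregationConfig()
    tp, w1 = _wrap(Xprev)
    ti, w2 = _wrap(Xi)
    tn, w3 = _wrap(Xnext)
    if not (tp.shape == ti.shape == tn.shape):
        raise ValueError("the three frames must share one shape")
    axes = tuple(range(ti.ndim))
    out = (
        cfg.alpha * _weight_frame_t(tp, ti, cfg, phi, axes)
        + cfg.gamma * ti
        + cfg.beta * _weight_frame_t(tn, ti, cfg, phi, axes)
    )
    return out if (w1 or w2 or w3) else out.data


def expected_output_frames(T: int, window_mode: str) -> int:
    """Aggregated frame count for an input of T frames."""
    if window_mode == "sliding":
        if T < 3:
            raise ValueError("sliding aggregation needs at least 3 frames")
        return T - 2
    if T % 3 != 0:
        raise ValueError("nonoverlap aggregation needs T divisible by 3")
    return T // 3


def aggregate_video(seq, cfg: AggregationConfig | None = None,
                    target_T: int | None = None,
                    phi: LearnablePhi | None = None):
    """Aggregate a whole clip; vectorized across windows.

    ``seq`` may be a :class:`FrameSequence`, a (T, C, H, W) array, or a
    (T, C, H, W) Tensor (the Tensor path keeps the operation differentiable
    when ``phi`` is trainable).  Returns the same kind as the input.
    """
    cfg = cfg or AggregationConfig()
    as_sequence = isinstance(seq, FrameSequence)
    raw = seq.frames if as_sequence else seq
    t, was_tensor = _wrap(raw)
    if t.ndim != 4:
        raise ValueError("expected (T, C, H, W) input")
    T = t.shape[0]
    out_T = expected_output_frames(T, cfg.window_mode)
    if target_T is not None and target_T != out_T:
        raise ValueError(
            f"{cfg.window_mode} aggregation of {T} frames yields {out_T} frames, "
            f"not target_T={target_T}"
        )
    if cfg.window_mode == "sliding":
        prev = t.narrow(0, 0, T - 2)
        ref = t.narrow(0, 1, T - 2)
        nxt = t.narrow(0, 2, T - 2)
    else:
        grouped = t.reshape(T // 3, 3, *t.shape[1:])
        prev = grouped.narrow(1, 0, 1).reshape(T // 3, *t.shape[1:])
        ref = grouped.narrow(1, 1, 1).reshape(T // 3, *t.shape[1:])
        nxt = grouped.narrow(1, 2, 1).reshape(T // 3, *t.shape[1:])
    axes = (1, 2, 3)  # per-frame weight maps over (C, H, W)
    out = (
        cfg.alpha * _weight_frame_t(prev, ref, cfg, phi, axes)
        + cfg.gamma * ref
        + cfg.beta * _weight_frame_t(nxt, ref, cfg, phi, axes)
    )
    if was_tensor:
        return out
    return FrameSequence(out.data) if as_sequence else out.data
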