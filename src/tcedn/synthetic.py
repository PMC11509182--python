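"""Seeded synthetic eye-region clips with severity-modulated motion.

The restricted interview corpora this tool targets cannot be redistributed,
so testing and the scaled-down study run on generated periocular video: a
smooth skin-toned strip with two dark elliptical eyes and brow bands,
animated with

* blink events — the eyelid closes over three frames, occluding the dark
  iris ellipse (eye-region mean intensity rises during a blink);
* a static brow offset that lowers the brows in proportion to severity
  (furrowed-brow appearance);
* global sub-pixel jitter (smoothed random walk) emulating head micro-motion;
* optional additive Gaussian pixel noise.

The scalar label is a BDI-II-scale severity in [0, 63].  Higher severity
means *less* facial motion — fewer blinks and smaller jitter — a clinically
motivated direction (psychomotor retardation, reduced expressivity); the
mapping is strictly monotone, which is what the recovery tests rely on.
Everything is deterministic given (severity, seed): the jitter path, blink
slots and noise field are drawn from fixed sub-streams of the seed so that
two clips differing only in severity share their randomness and differ only
through the monotone severity scalings.

The default 32 x 90 frame approximates the aspect of the 270 x 80 eye-strip
crop used with real interview video while keeping CPU tests fast; the full
geometry is available through :class:`SyntheticSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .aggregation import FrameSequence

__all__ = ["SyntheticSpec", "LabeledClip", "make_fixture", "generate_clip",
           "generate_dataset", "expected_blink_count", "count_blink_events",
           "motion_energy", "assign_splits"]


@dataclass
class SyntheticSpec:
    frame_shape: tuple = (32, 90)        # (H, W)
    frames_per_clip: int = 48            # 48 or 66, matching the sampling protocol
    blink_rate_range: tuple = (8.0, 2.0)  # events/clip at severity 0 -> 63
    brow_offset_gain: float = 0.06       # pixels of brow lowering per severity unit
    micro_motion_amp: float = 0.6        # RMS jitter in pixels at severity 0
    motion_floor: float = 0.25           # fraction of jitter kept at severity 63
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        H, W = self.frame_shape
        if H < 8 or W < 8:
            raise ValueError("frame_shape too small to render the eye strip")
        if self.frames_per_clip < 1:
            raise ValueError("frames_per_clip must be positive")
        if self.blink_rate_range[0] <= self.blink_rate_range[1]:
            raise ValueError("blink rate must decrease with severity")
        if not (0 < self.motion_floor <= 1):
            raise ValueError("motion_floor must lie in (0, 1]")


@dataclass
class LabeledClip:
    sequence: FrameSequence
    label: float

    def __post_init__(self):
        if not np.isfinite(self.label) or not (0 <= self.label <= 63):
            raise ValueError("severity label must lie in [0, 63]")


def expected_blink_count(severity: float, spec: SyntheticSpec) -> int:
    """Blink events per clip: linear in severity, rounded half-up."""
    b0, b1 = spec.blink_rate_range
    rate = b0 + (b1 - b0) * severity / 63.0
    return int(np.floor(rate + 0.5))


def _eye_geometry(spec: SyntheticSpec):
    H, W = spec.frame_shape
    cy = 0.52 * H
    centers = (0.32 * W, 0.68 * W)
    a = 0.085 * W          # horizontal semi-axis
    b = 0.16 * H           # vertical semi-axis
    brow_y = 0.22 * H
    brow_h = 0.07 * H
    return cy, centers, a, b, brow_y, brow_h


def _render_frame(spec: SyntheticSpec, dy: float, dx: float,
                  brow_off: float, closure: float) -> np.ndarray:
    H, W = spec.frame_shape
    yy = np.arange(H, dtype=np.float64)[:, None] - dy
    xx = np.arange(W, dtype=np.float64)[None, :] - dx
    cy, centers, a, b, brow_y, brow_h = _eye_geometry(spec)
    img = 0.62 + 0.05 * np.sin(2 * np.pi * xx / W) * np.cos(2 * np.pi * yy / H)
    # brow bands (lowered with severity)
    for cx in centers:
        by = brow_y + brow_off
        band = expit(3.0 * (yy - by)) * expit(-3.0 * (yy - by - brow_h))
        lateral = np.exp(-((xx - cx) / (2.2 * a)) ** 2)
        m = band * lateral
        img = img * (1 - 0.6 * m) + 0.30 * 0.6 * m
    # eyes; the lid closes by shrinking the visible vertical extent
    b_eff = b * max(1.0 - 0.92 * closure, 0.05)
    for cx in centers:
        d = ((yy - cy) / b_eff) ** 2 + ((xx - cx) / a) ** 2
        m = expit(-6.0 * (d - 1.0))
        img = img * (1 - m) + 0.12 * m
    return np.clip(img, 0.0, 1.0)


def _jitter_path(rng: np.random.Generator, T: int) -> np.ndarray:
    """Zero-mean smoothed random walk, unit RMS per component, shape (T, 2)."""
    steps = rng.normal(size=(T, 2))
    path = np.cumsum(steps, axis=0)
    kernel = np.ones(3) / 3.0
    for k in range(2):
        path[:, k] = np.convolve(path[:, k], kernel, mode="same")
    path -= path.mean(axis=0)
    rms = np.sqrt((path**2).mean(axis=0))
    rms[rms == 0] = 1.0
    return path / rms


def _blink_slots(rng: np.random.Generator, T: int, max_events: int) -> np.ndarray:
    """Blink centres: one per equal time segment, jittered by +-1 frame.

    Evenly spaced segments guarantee that all ``max_events`` centres fit with
    enough separation for the 3-frame blink profiles to stay distinct, while
    the jitter keeps timings clip-specific.  A lower event count uses a
    prefix of the same slots, so clips differing only in severity share
    their blink times.
    """
    edges = np.linspace(0, T, max_events + 1)
    centres = []
    for k in range(max_events):
        mid = 0.5 * (edges[k] + edges[k + 1])
        c = int(round(mid + rng.uniform(-1.0, 1.0)))
        centres.append(min(max(c, 1), T - 2))
    return rng.permutation(np.array(centres))


def generate_clip(severity: float, spec: SyntheticSpec | None = None,
                  seed: int = 0) -> LabeledClip:
    """Render one labelled clip; fully deterministic given (severity, seed)."""
    spec = spec or SyntheticSpec()
    if not np.isfinite(severity) or not (0 <= severity <= 63):
        raise ValueError("severity must lie in [0, 63]")
    T = spec.frames_per_clip
    H, W = spec.frame_shape
    sev_f = severity / 63.0

    rng_motion = np.random.default_rng([seed, 1])
    rng_blink = np.random.default_rng([seed, 2])
    rng_noise = np.random.default_rng([seed, 3])

    amp = spec.micro_motion_amp * (1.0 - (1.0 - spec.motion_floor) * sev_f)
    path = _jitter_path(rng_motion, T) * amp

    b0, _ = spec.blink_rate_range
    slots = _blink_slots(rng_blink, T, max_events=int(np.floor(b0 + 0.5)))
    n_blinks = min(expected_blink_count(severity, spec), len(slots))
    closure = np.zeros(T)
    for c in slots[:n_blinks]:
        for off, val in ((-1, 0.5), (0, 1.0), (1, 0.5)):
            t = c + off
            if 0 <= t < T:
                closure[t] = max(closure[t], val)

    brow_off = spec.brow_offset_gain * severity
    frames = np.empty((T, 1, H, W))
    for t in range(T):
        frames[t, 0] = _render_frame(spec, path[t, 0], path[t, 1],
                                     brow_off, closure[t])
    if spec.noise_sigma > 0:
        frames = np.clip(
            frames + rng_noise.normal(0.0, spec.noise_sigma, size=frames.shape),
            0.0, 1.0)
    return LabeledClip(FrameSequence(frames), float(severity))


def motion_energy(frames: np.ndarray) -> float:
    """Mean absolute inter-frame difference — the generator's motion statistic."""
    frames = np.asarray(frames)
    if frames.shape[0] < 2:
        return 0.0
    return float(np.mean(np.abs(np.diff(frames, axis=0))))


def count_blink_events(frames: np.ndarray, spec: SyntheticSpec) -> int:
    """Count eyelid-closure events from the eye-region intensity trace.

    During a blink the dark iris ellipses are covered by skin, so the mean
    intensity over the eye regions rises; events are maximal runs above a
    mid-range threshold.
    """
    frames = np.asarray(frames)
    H, W = spec.frame_shape
    cy, centers, a, b, _, _ = _eye_geometry(spec)
    yy = np.arange(H)[:, None]
    xx = np.arange(W)[None, :]
    mask = np.zeros((H, W), dtype=bool)
    for cx in centers:
        mask |= (((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2) <= 1.0
    trace = frames[:, 0][:, mask].mean(axis=1)
    lo, hi = trace.min(), trace.max()
    if hi - lo < 1e-6:
        return 0
    thr = lo + 0.5 * (hi - lo)
    above = trace > thr
    return int(np.sum(above[1:] & ~above[:-1]) + above[0])


def assign_splits(n: int, fractions=(0.70, 0.15, 0.15)) -> list:
    """Sequential train/val/test assignment with half-up rounded counts."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(np.floor(fractions[0] * n + 0.5))
    n_val = int(np.floor(fractions[1] * n + 0.5))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return (["train"] * n_train + ["val"] * n_val
            + ["test"] * (n - n_train - n_val))


def generate_dataset(n: int, spec: SyntheticSpec | None = None, seed: int = 0,
                     fractions=(0.70, 0.15, 0.15)):
    """Generate ``n`` labelled clips plus a manifest with a declared split.

    Severities are drawn uniformly over [0, 63]; each clip gets its own
    sub-seed derived from ``seed``.  Returns ``(clips, manifest)`` where the
    manifest is a DataFrame with columns clip_id, bdi_score, split.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng([seed, 0])
    severities = rng.uniform(0.0, 63.0, size=n)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    clips = [generate_clip(severities[i], spec, seed=int(child_seeds[i]))
             for i in range(n)]
    manifest = pd.DataFrame({
        "clip_id": [f"clip_{i:04d}" for i in range(n)],
        "bdi_score": severities,
        "split": assign_splits(n, fractions),
    })
    return clips, manifest


def make_fixture(kind: str, seed: int = 0, value: float = 0.5) -> FrameSequence:
    """Tiny hand-checkable sequences for unit tests of the aggregation and
    difference operators."""
    if kind == "constant":
        return FrameSequence(np.full((6, 1, 3, 3), value))
    if kind == "ramp":
        t = np.arange(6, dtype=float).reshape(6, 1, 1, 1)
        return FrameSequence(np.broadcast_to(t, (6, 1, 3, 3)).copy())
    if kind == "two_by_two_random":
        rng = np.random.default_rng(seed)
        return FrameSequence(rng.uniform(0.0, 1.0, size=(6, 1, 2, 2)))
    raise ValueError(f"unknown fixture kind {kind!r}")
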