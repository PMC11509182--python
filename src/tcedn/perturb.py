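"""Input perturbations for robustness evaluation.

Mirrors the robustness protocol of clip-level stress tests: in-plane frame
rotation (30/60/90 degrees about the frame centre, zero fill), additive
Gaussian pixel noise, additive uniform ("random") noise, and a randomly
sized, randomly placed zeroed rectangle per clip (occlusion).  Every
perturbation is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .aggregation import FrameSequence

__all__ = ["PerturbationSpec", "perturb", "standard_suite"]

_KINDS = ("identity", "rotate30", "rotate60", "rotate90",
          "gaussian_noise", "random_noise", "random_occlusion")


@dataclass
class PerturbationSpec:
    kind: str = "identity"
    sigma: float = 0.05            # Gaussian noise std, pixel units
    amplitude: float = 0.05        # uniform noise half-range
    occlusion_frac: tuple = (0.1, 0.3)   # side length range, fraction of frame side
    angle: float | None = None     # explicit rotation angle override
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")

    @property
    def label(self) -> str:
        return {
            "identity": "Unperturbed",
            "rotate30": "Image Rotation by 30 Degrees",
            "rotate60": "Image Rotation by 60 Degrees",
            "rotate90": "Image Rotation by 90 Degrees",
            "gaussian_noise": "Image with Gaussian Noise",
            "random_noise": "Image with Random Noise",
            "random_occlusion": "Image with Random Occlusion",
        }[self.kind]


def _rotation_angle(spec: PerturbationSpec) -> float:
    if spec.angle is not None:
        return float(spec.angle)
    return {"rotate30": 30.0, "rotate60": 60.0, "rotate90": 90.0}[spec.kind]


def perturb(seq, spec: PerturbationSpec):
    """Apply one perturbation to a clip; returns the same kind as the input."""
    as_sequence = isinstance(seq, FrameSequence)
    frames = np.array(seq.frames if as_sequence else seq, dtype=np.float64)
    if frames.ndim != 4:
        raise ValueError("expected a (T, C, H, W) clip")
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "identity":
        out = frames
    elif spec.kind.startswith("rotate"):
        angle = _rotation_angle(spec)
        if angle % 360 == 0:
            out = frames
        else:
            out = ndimage.rotate(frames, angle, axes=(3, 2), reshape=False,
                                 order=1, mode="constant", cval=0.0)
            out = np.clip(out, 0.0, 1.0)
    elif spec.kind == "gaussian_noise":
        out = frames if spec.sigma == 0 else np.clip(
            frames + rng.normal(0.0, spec.sigma, size=frames.shape), 0.0, 1.0)
    elif spec.kind == "random_noise":
        out = frames if spec.amplitude == 0 else np.clip(
            frames + rng.uniform(-spec.amplitude, spec.amplitude,
                                 size=frames.shape), 0.0, 1.0)
    elif spec.kind == "random_occlusion":
        T, C, H, W = frames.shape
        lo, hi = spec.occlusion_frac
        side = min(H, W)
        oh = max(1, int(round(rng.uniform(lo, hi) * side)))
        ow = max(1, int(round(rng.uniform(lo, hi) * side)))
        y0 = int(rng.integers(0, H - oh + 1))
        x0 = int(rng.integers(0, W - ow + 1))
        out = frames.copy()
        out[:, :, y0:y0 + oh, x0:x0 + ow] = 0.0
    else:  # pragma: no cover
        raise ValueError(spec.kind)

    return FrameSequence(out) if as_sequence else out


def standard_suite(seed: int = 0, sigma: float = 0.05,
                   amplitude: float = 0.05) -> list:
    """The six stress-test rows plus the unperturbed reference row."""
    return [
        PerturbationSpec("identity", seed=seed),
        PerturbationSpec("rotate30", seed=seed),
        PerturbationSpec("rotate60", seed=seed),
        PerturbationSpec("rotate90", seed=seed),
        PerturbationSpec("gaussian_noise", sigma=sigma, seed=seed),
        PerturbationSpec("random_noise", amplitude=amplitude, seed=seed),
        PerturbationSpec("random_occlusion", seed=seed),
    ]
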