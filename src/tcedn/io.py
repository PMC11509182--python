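"""Clip and manifest I/O.

Clips live on disk either as a directory of numbered PNG frames or as one
packed ``.npz`` archive with a single time-major array named ``frames``
(shape (T, C, H, W), float32 in [0, 1]).  A dataset is a manifest CSV with
columns ``clip_path, bdi_score, split`` plus the clips it points to.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .aggregation import FrameSequence

__all__ = ["save_clip", "load_clip", "write_dataset", "load_manifest_dataset"]


def save_clip(path, frames, fmt: str = "npz") -> Path:
    """Write one clip as ``<path>.npz`` or a ``<path>/`` directory of PNGs."""
    frames = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    path = Path(path)
    if fmt == "npz":
        out = path.with_suffix(".npz")
        np.savez_compressed(out, frames=frames.astype(np.float32))
        return out
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(frames):
            img = np.clip(frame, 0.0, 1.0)
            img = (img * 255).round().astype(np.uint8)
            img = img[0] if img.shape[0] == 1 else img.transpose(1, 2, 0)
            iio.imwrite(path / f"frame_{t:04d}.png", img)
        return path
    raise ValueError(f"unknown clip format {fmt!r}")


def load_clip(path) -> np.ndarray:
    """Read a clip back as a float (T, C, H, W) array in [0, 1]."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as archive:
            return np.asarray(archive["frames"], dtype=np.float64)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files under {path}")
        frames = []
        for f in files:
            img = iio.imread(f).astype(np.float64) / 255.0
            if img.ndim == 2:
                img = img[None]
            else:
                img = img.transpose(2, 0, 1)
            frames.append(img)
        return np.stack(frames)
    raise FileNotFoundError(path)


def write_dataset(out_dir, clips, manifest: pd.DataFrame, fmt: str = "npz") -> Path:
    """Write clips plus ``manifest.csv`` (clip_path, bdi_score, split)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for clip_id, clip in zip(manifest["clip_id"], clips):
        seq = clip.sequence if hasattr(clip, "sequence") else clip
        written = save_clip(out_dir / clip_id, seq, fmt=fmt)
        paths.append(written.name)
    out = manifest.copy()
    out["clip_path"] = paths
    out = out[["clip_path", "bdi_score", "split"]]
    out.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def load_manifest_dataset(manifest_csv, root=None):
    """Load (clips, labels, splits) from a manifest CSV."""
    manifest_csv = Path(manifest_csv)
    root = Path(root) if root is not None else manifest_csv.parent
    table = pd.read_csv(manifest_csv)
    for col in ("clip_path", "bdi_score", "split"):
        if col not in table.columns:
            raise ValueError(f"manifest is missing the {col!r} column")
    clips = [FrameSequence(load_clip(root / p)) for p in table["clip_path"]]
    return clips, table["bdi_score"].to_numpy(dtype=float), \
        table["split"].to_numpy(dtype=object)
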