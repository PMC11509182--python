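"""Regression metrics, BDI-II severity banding, and per-clip error analysis."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["mse_loss", "mae", "rmse", "severity_band", "SEVERITY_BANDS",
           "band_index", "MetricsReport", "compute_report"]

#: Inclusive integer BDI-II score ranges of the four severity bands.
SEVERITY_BANDS = (
    ("minimal", 0, 13),
    ("mild", 14, 19),
    ("moderate", 20, 28),
    ("severe", 29, 63),
)

BAND_NAMES = tuple(name for name, _, _ in SEVERITY_BANDS)


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions differ in length")
    return y, yhat


def mse_loss(y, yhat) -> float:
    """Mean squared error (1/n) sum (y_i - yhat_i)^2."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def mae(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    return math.sqrt(mse_loss(y, yhat))


def band_index(score: float) -> int:
    """0-based index of the severity band a BDI-II score falls into.

    Non-integer scores are rounded half-up (only integer totals occur on the
    real instrument); out-of-range values are clamped to [0, 63] first.
    """
    if not np.isfinite(score):
        raise ValueError("severity score must be finite")
    s = min(max(float(score), 0.0), 63.0)
    s = math.floor(s + 0.5)
    for i, (_, lo, hi) in enumerate(SEVERITY_BANDS):
        if lo <= s <= hi:
            return i
    raise AssertionError("unreachable: bands partition [0, 63]")


def severity_band(score: float) -> str:
    """Severity band name: minimal 0-13, mild 14-19, moderate 20-28, severe 29-63."""
    return BAND_NAMES[band_index(score)]


@dataclass
class MetricsReport:
    """Per-clip evaluation summary of a trained severity regressor."""

    mae: float
    rmse: float
    abs_errors: np.ndarray
    frac_below: dict
    band_confusion: np.ndarray          # rows: true band, cols: predicted band
    predictions: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if self.rmse < self.mae - 1e-9:
            raise AssertionError("RMSE < MAE violates Jensen's inequality")

    @property
    def n_clips(self) -> int:
        return int(self.abs_errors.size)

    def sorted_error_curve(self) -> np.ndarray:
        """Absolute errors sorted ascending (error-distribution view)."""
        return np.sort(self.abs_errors)

    def score_ordered_errors(self) -> np.ndarray:
        """Absolute errors ordered by true severity, lowest to highest."""
        return self.abs_errors[np.argsort(self.labels, kind="stable")]

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "n_clips": self.n_clips,
            "frac_below": {str(k): v for k, v in self.frac_below.items()},
            "band_confusion": self.band_confusion.tolist(),
            "abs_errors": self.abs_errors.tolist(),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_report(labels, predictions,
                   thresholds=(2.0, 4.0, 6.0, 8.0, 10.0)) -> MetricsReport:
    """Build a :class:`MetricsReport` from per-clip labels and predictions."""
    y, yhat = _check_pair(labels, predictions)
    errs = np.abs(y - yhat)
    confusion = np.zeros((4, 4), dtype=int)
    for yt, yp in zip(y, yhat):
        confusion[band_index(yt), band_index(yp)] += 1
    frac = {float(t): float(np.mean(errs < t)) for t in thresholds}
    return MetricsReport(
        mae=mae(y, yhat), rmse=rmse(y, yhat), abs_errors=errs,
        frac_below=frac, band_confusion=confusion,
        predictions=yhat, labels=y,
    )
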