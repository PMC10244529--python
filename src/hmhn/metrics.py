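"""Evaluation metrics and the BDI-II severity mapping.

MAE and RMSE are the standard depression-challenge metrics:

    MAE  = (1/M) Σ |ℓ̂_j − ℓ_j|
    RMSE = sqrt( (1/M) Σ (ℓ̂_j − ℓ_j)² )

The Beck Depression Inventory-II total (0–63) maps onto four clinical
severity bands: 0–13 none or minimal, 14–19 mild, 20–28 moderate,
29–63 severe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["mae", "rmse", "SeverityBand", "SEVERITY_BANDS", "severity_from_score",
           "band_confusion"]


def _validate(truth, pred) -> tuple:
    truth = np.asarray(truth, dtype=np.float64).reshape(-1)
    pred = np.asarray(pred, dtype=np.float64).reshape(-1)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: truth {truth.shape}, pred {pred.shape}")
    if truth.size < 1:
        raise ValueError("need at least one sample")
    return truth, pred


def mae(truth, pred) -> float:
    """Mean absolute error between true and predicted BDI-II scores."""
    truth, pred = _validate(truth, pred)
    return float(np.mean(np.abs(pred - truth)))


def rmse(truth, pred) -> float:
    """Root-mean-square error between true and predicted BDI-II scores."""
    truth, pred = _validate(truth, pred)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


@dataclass(frozen=True)
class SeverityBand:
    label: str
    low: int      # inclusive
    high: int     # inclusive


SEVERITY_BANDS = (
    SeverityBand("None or minimal", 0, 13),
    SeverityBand("Mild", 14, 19),
    SeverityBand("Moderate", 20, 28),
    SeverityBand("Severe", 29, 63),
)


def severity_from_score(score: float) -> SeverityBand:
    """Clinical severity band for a (possibly non-integer) BDI-II score.

    The score is clamped to [0, 63] and rounded half-up before banding, since
    the bands are defined on integer cut-offs.
    """
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    s = int(math.floor(min(max(float(score), 0.0), 63.0) + 0.5))
    s = min(s, 63)
    for band in SEVERITY_BANDS:
        if band.low <= s <= band.high:
            return band
    raise AssertionError("bands partition 0..63")   # pragma: no cover


def band_confusion(truth, pred) -> np.ndarray:
    """4×4 confusion matrix of severity bands (rows: true, cols: predicted)."""
    truth, pred = _validate(truth, pred)
    labels = [b.label for b in SEVERITY_BANDS]
    m = np.zeros((4, 4), dtype=int)
    for t, p in zip(truth, pred):
        m[labels.index(severity_from_score(t).label),
          labels.index(severity_from_score(p).label)] += 1
    return m
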