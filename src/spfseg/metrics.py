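"""Segmentation evaluation: pixel accuracy, Dice, Jaccard and boundary F1.

All metrics compare a binary segmentation mask against a binary ground
truth on the same grid and lie in [0, 1].  Dice and Jaccard measure
region overlap (with ``jaccard = dice / (2 - dice)``); the BF score is
the harmonic mean of boundary precision and recall, where a boundary
pixel counts as matched if the other mask's boundary passes within
``distance_tol`` pixels (Euclidean).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy",
    "dice",
    "jaccard",
    "bf_score",
    "evaluate_masks",
]

#: Matching distance (pixels) for the boundary F1 score.
DEFAULT_DISTANCE_TOL = 2.0


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    dice: float
    jaccard: float
    bf_score: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        return "\n".join(f"{k} = {v:.6f}" for k, v in asdict(self).items())


def _as_bool_pair(mask: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = np.asarray(mask).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if mask.shape != truth.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape} vs truth {truth.shape}")
    return mask, truth


def confusion(mask: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts with foreground = True."""
    mask, truth = _as_bool_pair(mask, truth)
    tp = int(np.sum(mask & truth))
    tn = int(np.sum(~mask & ~truth))
    fp = int(np.sum(mask & ~truth))
    fn = int(np.sum(~mask & truth))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(counts: ConfusionCounts) -> float:
    """Fraction of correctly labelled pixels, ``(TP+TN)/total``."""
    if counts.total <= 0:
        raise ValueError("confusion counts sum to zero")
    return (counts.TP + counts.TN) / counts.total


def dice(mask: np.ndarray, truth: np.ndarray) -> float:
    """Overlap index ``2|A & B| / (|A| + |B|)``; 1.0 when both are empty."""
    mask, truth = _as_bool_pair(mask, truth)
    denom = int(mask.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(mask & truth)) / denom


def jaccard(mask: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union; 1.0 when both are empty."""
    mask, truth = _as_bool_pair(mask, truth)
    union = int(np.sum(mask | truth))
    if union == 0:
        return 1.0
    return int(np.sum(mask & truth)) / union


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (outside counts as bg)."""
    four = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=four, border_value=0)
    return mask & ~interior


def bf_score(
    mask: np.ndarray, truth: np.ndarray, distance_tol: float = DEFAULT_DISTANCE_TOL
) -> float:
    """Boundary F1: harmonic mean of boundary precision and recall.

    ``alpha1`` is the fraction of mask-boundary pixels within
    ``distance_tol`` of the truth boundary, ``alpha2`` the converse, and
    the score is ``2 a1 a2 / (a1 + a2)`` (0 when both vanish).
    """
    mask, truth = _as_bool_pair(mask, truth)
    b_mask = _boundary(mask)
    b_truth = _boundary(truth)
    if not b_mask.any() or not b_truth.any():
        raise ValueError("bf_score requires non-empty boundaries on both masks")
    # Distance of every pixel to the nearest boundary pixel of the other mask.
    d_to_truth = ndimage.distance_transform_edt(~b_truth)
    d_to_mask = ndimage.distance_transform_edt(~b_mask)
    a1 = float(np.mean(d_to_truth[b_mask] <= distance_tol))
    a2 = float(np.mean(d_to_mask[b_truth] <= distance_tol))
    if a1 + a2 == 0:
        return 0.0
    return 2.0 * a1 * a2 / (a1 + a2)


def evaluate_masks(
    mask: np.ndarray, truth: np.ndarray, distance_tol: float = DEFAULT_DISTANCE_TOL
) -> MetricsReport:
    """Full evaluation of a segmentation against ground truth."""
    return MetricsReport(
        accuracy=accuracy(confusion(mask, truth)),
        dice=dice(mask, truth),
        jaccard=jaccard(mask, truth),
        bf_score=bf_score(mask, truth, distance_tol),
    )
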