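"""Segmentation-quality measures used as log features and acceptance checks.

All mask metrics operate on pairs of equal-shape binary arrays
``(predicted, reference)``.  Ratio metrics (Dice, Jaccard, RAVD, object
TPR) require a non-empty reference foreground and raise
:class:`UndefinedMetricError` otherwise; rank metrics (ROC AUC) require
both classes present in the reference.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "UndefinedMetricError",
    "dice",
    "jaccard",
    "rand_index",
    "ravd",
    "mse",
    "obj_tpr",
    "obj_tnr",
    "roc_auc",
    "log_loss",
    "dice_trajectory",
    "trajectory_auc",
]

LOG_LOSS_CLIP = 1e-6


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for a degenerate reference."""


def _pair(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(pred).astype(bool)
    b = np.asarray(ref).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(pred, ref) -> float:
    """Sørensen–Dice overlap 2|A∩B| / (|A| + |B|)."""
    a, b = _pair(pred, ref)
    if not b.any():
        raise UndefinedMetricError("dice undefined for empty reference")
    denom = a.sum() + b.sum()
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def jaccard(pred, ref) -> float:
    """Intersection over union |A∩B| / |A∪B|."""
    a, b = _pair(pred, ref)
    if not b.any():
        raise UndefinedMetricError("jaccard undefined for empty reference")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def rand_index(pred, ref) -> float:
    """Rand index of the two binary pixel partitions (pair counting).

    Fraction of pixel pairs on which the two labelings agree (both pairs
    together or both apart), computed from the 2x2 contingency table.
    """
    a, b = _pair(pred, ref)
    n = a.size
    if n < 2:
        raise UndefinedMetricError("rand index needs at least two pixels")
    # contingency counts over the four label combinations
    n11 = float(np.logical_and(a, b).sum())
    n10 = float(np.logical_and(a, ~b).sum())
    n01 = float(np.logical_and(~a, b).sum())
    n00 = float(np.logical_and(~a, ~b).sum())

    def c2(x: float) -> float:
        return x * (x - 1.0) / 2.0

    same_both = c2(n11) + c2(n10) + c2(n01) + c2(n00)
    same_a = c2(n11 + n10) + c2(n01 + n00)
    same_b = c2(n11 + n01) + c2(n10 + n00)
    total = c2(float(n))
    # agreements = pairs together in both + pairs apart in both
    agree = same_both + (total - same_a - same_b + same_both)
    return float(agree / total)


def ravd(pred, ref) -> float:
    """Relative absolute area difference |A_pred − A_ref| / A_ref."""
    a, b = _pair(pred, ref)
    area_ref = b.sum()
    if area_ref == 0:
        raise UndefinedMetricError("ravd undefined for empty reference")
    return float(abs(int(a.sum()) - int(area_ref)) / area_ref)


def mse(pred, ref) -> float:
    """Mean squared pixel error between the binary masks (in [0, 1])."""
    a, b = _pair(pred, ref)
    return float(np.mean((a.astype(float) - b.astype(float)) ** 2))


def obj_tpr(pred, ref) -> float:
    """Foreground (object) true-positive rate."""
    a, b = _pair(pred, ref)
    if not b.any():
        raise UndefinedMetricError("object TPR undefined for empty reference")
    return float(np.logical_and(a, b).sum() / b.sum())


def obj_tnr(pred, ref) -> float:
    """Background true-negative rate."""
    a, b = _pair(pred, ref)
    neg = (~b).sum()
    if neg == 0:
        raise UndefinedMetricError("object TNR undefined for all-foreground reference")
    return float(np.logical_and(~a, ~b).sum() / neg)


def roc_auc(score_map, ref) -> float:
    """Rank-based AUC of a real-valued foreground score map (ties averaged)."""
    scores = np.asarray(score_map, dtype=np.float64).ravel()
    labels = np.asarray(ref).astype(bool).ravel()
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise UndefinedMetricError("ROC AUC undefined for one-class reference")
    return float(roc_auc_score(labels, scores))


def log_loss(prob_map, ref, clip: float = LOG_LOSS_CLIP) -> float:
    """Mean cross-entropy of a foreground probability map."""
    p = np.clip(np.asarray(prob_map, dtype=np.float64).ravel(), clip, 1.0 - clip)
    y = np.asarray(ref).astype(float).ravel()
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_trajectory(log) -> list[tuple[int, float]]:
    """Per-interaction Dice sequence of an interaction log.

    Returns ``[(n, dice_after), ...]`` over the events that changed the
    segmentation (scribbles, option choices, point commits, long presses
    and undos).
    """
    traj = []
    n = 0
    for ev in log.events:
        if ev.dice_after is not None:
            n += 1
            traj.append((n, float(ev.dice_after)))
    return traj


def trajectory_auc(traj: list[tuple[int, float]]) -> float:
    """Mean Dice over the trajectory — an area-under-trajectory summary
    normalized by its length (0 for an empty trajectory)."""
    if not traj:
        return 0.0
    return float(np.mean([d for _, d in traj]))
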