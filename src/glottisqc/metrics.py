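"""Mask representation, IoU, and classification/regression metrics.

Masks are plain 2-D boolean :class:`numpy.ndarray` objects; frames are 2-D
float arrays with values in [0, 1]. The helpers here validate and coerce
those conventions; everything downstream (perturbation, training,
evaluation) builds on :func:`compute_iou` and the accept/decline threshold.

Conventions
-----------
* IoU of two empty masks is 1.0 (a correct "nothing to segment" call);
  IoU when exactly one mask is empty is 0.0.
* A score is *accepted* iff ``score >= t`` (equality accepts).
* The positive class of the accept/decline classifier is the *failed*
  segmentation (true IoU below the threshold), so sensitivity is the
  failure-detection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "as_mask",
    "as_frame",
    "ScoredSample",
    "ConfusionCounts",
    "compute_iou",
    "classify_iou",
    "confusion",
    "regression_metrics",
    "roc_sweep",
    "interval_stats",
]

ACCEPTED = "accepted"
DECLINED = "declined"


def as_mask(arr) -> np.ndarray:
    """Coerce *arr* to a validated 2-D boolean mask.

    Accepts boolean arrays, {0, 1} integer arrays and {0, 255} 8-bit
    PNG-style arrays. Anything else is rejected.
    """
    a = np.asarray(arr)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"mask must be a non-empty 2-D array, got shape {a.shape}")
    if a.dtype == bool:
        return a
    vals = np.unique(a)
    if np.isin(vals, (0, 1)).all():
        return a.astype(bool)
    if np.isin(vals, (0, 255)).all():
        return a > 0
    raise ValueError("mask values must be binary (bool, {0,1} or {0,255})")


def as_frame(arr) -> np.ndarray:
    """Coerce *arr* to a validated 2-D float frame with values in [0, 1]."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {a.shape}")
    if a.size == 0:
        raise ValueError("frame must be non-empty")
    if a.min() < 0.0 or a.max() > 1.0:
        raise ValueError(
            f"frame values must lie in [0, 1], got [{a.min():.4g}, {a.max():.4g}]"
        )
    return a


@dataclass
class ScoredSample:
    """A (frame, ground-truth mask, candidate mask, exact IoU) record.

    ``iou`` is always the *recomputed* IoU of ``candidate_mask`` against
    ``gt_mask``, never the sampling target that produced the candidate.
    """

    frame: np.ndarray
    gt_mask: np.ndarray
    candidate_mask: np.ndarray
    iou: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frame = as_frame(self.frame)
        self.gt_mask = as_mask(self.gt_mask)
        self.candidate_mask = as_mask(self.candidate_mask)
        if not (self.frame.shape == self.gt_mask.shape == self.candidate_mask.shape):
            raise ValueError(
                "frame/gt/candidate shapes differ: "
                f"{self.frame.shape}, {self.gt_mask.shape}, {self.candidate_mask.shape}"
            )
        expected = compute_iou(self.candidate_mask, self.gt_mask)
        if self.iou != expected:
            raise ValueError(
                f"stored IoU {self.iou!r} does not equal recomputed IoU {expected!r}"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts with *failed* (IoU < t) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        """Failure-detection rate tp/(tp+fn); NaN when no true failures."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        """True-accept rate tn/(tn+fp); NaN when no true accepts."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


def compute_iou(candidate, gt) -> float:
    """Intersection over union TP/(TP+FP+FN) of two same-shape binary masks.

    Both masks empty returns 1.0; exactly one empty returns 0.0.
    """
    a = as_mask(candidate)
    b = as_mask(gt)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return inter / union


def classify_iou(score: float, t: float) -> str:
    """Threshold a quality score: ``accepted`` iff ``score >= t``."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold t must lie in (0, 1), got {t}")
    return ACCEPTED if score >= t else DECLINED


def confusion(pred_scores: Sequence[float], true_ious: Sequence[float], t: float) -> ConfusionCounts:
    """Confusion counts at threshold *t*, positive class = failed (IoU < t)."""
    pred = np.asarray(pred_scores, dtype=np.float64)
    true = np.asarray(true_ious, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("confusion requires at least one sample")
    pred_fail = pred < t
    true_fail = true < t
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred_fail & true_fail)),
        fp=int(np.count_nonzero(pred_fail & ~true_fail)),
        tn=int(np.count_nonzero(~pred_fail & ~true_fail)),
        fn=int(np.count_nonzero(~pred_fail & true_fail)),
    )


def regression_metrics(pred_scores, true_ious) -> tuple[float, float]:
    """Return (MSE, MAE) of predicted scores against true IoUs."""
    pred = np.asarray(pred_scores, dtype=np.float64)
    true = np.asarray(true_ious, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("regression_metrics requires at least one sample")
    err = pred - true
    return float(np.mean(err**2)), float(np.mean(np.abs(err)))


def roc_sweep(
    pred_scores,
    true_ious,
    t_ground: float,
    inference_thresholds: Sequence[float],
) -> list[tuple[float, float, float]]:
    """ROC points for the failure detector over a grid of inference thresholds.

    Ground truth is binarized once at ``t_ground`` (positive = failed,
    true IoU < t_ground). At each inference threshold ``s`` a sample is
    *declared* failed when its predicted score is below ``s``; raising ``s``
    relaxes the declaration, so TPR and FPR are both non-decreasing along
    the sorted threshold grid.

    Returns a list of ``(fpr, tpr, threshold)``. When the ground truth has
    no positives (or no negatives) the undefined rate is NaN, never a
    silent 0.
    """
    pred = np.asarray(pred_scores, dtype=np.float64)
    true = np.asarray(true_ious, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    thr = np.asarray(inference_thresholds, dtype=np.float64)
    if np.any(np.diff(thr) < 0):
        raise ValueError("inference_thresholds must be sorted ascending")
    pos = true < t_ground
    n_pos = int(np.count_nonzero(pos))
    n_neg = int(pos.size - n_pos)
    out = []
    for s in thr:
        declared = pred < s
        tpr = float(np.count_nonzero(declared & pos)) / n_pos if n_pos else float("nan")
        fpr = float(np.count_nonzero(declared & ~pos)) / n_neg if n_neg else float("nan")
        out.append((fpr, tpr, float(s)))
    return out


def roc_auc(points: Sequence[tuple[float, float, float]]) -> float:
    """Trapezoidal area under a :func:`roc_sweep` curve.

    The curve is closed at (0,0) and (1,1) before integration.
    """
    fpr = np.array([p[0] for p in points], dtype=np.float64)
    tpr = np.array([p[1] for p in points], dtype=np.float64)
    if np.isnan(fpr).any() or np.isnan(tpr).any():
        raise ValueError("AUC undefined: ground truth lacks one of the classes")
    order = np.argsort(fpr, kind="stable")
    fpr = np.concatenate([[0.0], fpr[order], [1.0]])
    tpr = np.concatenate([[0.0], tpr[order], [1.0]])
    return float(np.trapezoid(tpr, fpr))


def interval_stats(pred_scores, true_ious, bin_edges, t: float = 0.6) -> list[dict]:
    """Per-interval diagnostics stratified by the *true* IoU.

    ``bin_edges`` must partition [0, 1] ascending. Each returned dict holds
    ``lo``, ``hi``, ``count`` and — for non-empty bins — ``mae`` (mean
    |pred - true|) and ``accuracy`` (binary accept/decline agreement at
    threshold *t*); empty bins carry ``mae = accuracy = None``.
    The final bin is closed on the right so a true IoU of exactly 1 counts.
    """
    pred = np.asarray(pred_scores, dtype=np.float64)
    true = np.asarray(true_ious, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly ascending with >= 2 entries")
    rows = []
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        last = i == edges.size - 2
        sel = (true >= lo) & ((true <= hi) if last else (true < hi))
        row = {"lo": float(lo), "hi": float(hi), "count": int(np.count_nonzero(sel))}
        if row["count"] == 0:
            row["mae"] = None
            row["accuracy"] = None
        else:
            p, y = pred[sel], true[sel]
            row["mae"] = float(np.mean(np.abs(p - y)))
            row["accuracy"] = float(np.mean((p >= t) == (y >= t)))
        rows.append(row)
    return rows
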