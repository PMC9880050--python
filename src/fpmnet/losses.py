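"""Dice pixel-classification loss and the segmentation statistics
SE / SP / Acc / AUC.

The dice loss for one image with predicted vessel probabilities ``Q`` and
binary ground truth ``R`` is::

    L = 1 - 2 * sum(Q * R) / (sum(Q**2) + sum(R**2))

(the squared-denominator soft-Dice form; since ``R`` is binary,
``R**2 == R``).  It is 0 exactly for a perfect binary match and robust to
the heavy vessel/background class imbalance of fundus images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score


class MetricError(ValueError):
    """A metric is undefined (zero denominator) or its inputs are invalid."""


def dice_loss(pred_probs: np.ndarray, truth: np.ndarray) -> float:
    """Dice loss between vessel probabilities ``Q`` in [0,1] and a binary
    mask ``R``; returns a scalar in [0, 1].

    The degenerate all-zero/all-zero case (empty truth matched by an empty
    prediction) returns 0 with a warning.
    """
    q = np.asarray(pred_probs, dtype=np.float64)
    r = np.asarray(truth, dtype=np.float64)
    if q.shape != r.shape:
        raise MetricError(f"shape mismatch: {q.shape} vs {r.shape}")
    if q.min() < 0 or q.max() > 1:
        raise MetricError("probabilities must lie in [0, 1]")
    if not np.isin(r, (0, 1)).all():
        raise MetricError("truth mask must be binary")
    denom = float((q * q).sum() + r.sum())
    if denom == 0.0:
        warnings.warn("dice_loss: empty prediction matches empty truth; "
                      "returning 0", stacklevel=2)
        return 0.0
    return 1.0 - 2.0 * float((q * r).sum()) / denom


def dice_loss_with_grad(pred_probs: np.ndarray,
                        truth: np.ndarray) -> tuple[float, np.ndarray]:
    """Dice loss and its gradient with respect to ``Q`` (training path)."""
    q = np.asarray(pred_probs, dtype=np.float64)
    r = np.asarray(truth, dtype=np.float64)
    s = float((q * r).sum())
    denom = float((q * q).sum() + r.sum())
    if denom == 0.0:
        return 0.0, np.zeros_like(q)
    loss = 1.0 - 2.0 * s / denom
    grad = -(2.0 * r * denom - 2.0 * s * 2.0 * q) / (denom * denom)
    return loss, grad


def batch_dice_from_logits(logits: np.ndarray,
                           truth: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-image dice loss from 2-class logits ``(N,2,H,W)`` and masks
    ``(N,H,W)``; returns the loss and its gradient w.r.t. the logits.

    The loss is computed on the continuous vessel-class softmax probability,
    not on a thresholded mask.
    """
    n = logits.shape[0]
    z = logits.astype(np.float64)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    q = probs[:, 1]
    losses = np.empty(n)
    dq = np.empty_like(q)
    for i in range(n):
        losses[i], dq[i] = dice_loss_with_grad(q[i], truth[i])
    dq /= n
    # chain through the 2-class softmax: dq/dz1 = q(1-q), dq/dz0 = -q(1-q)
    jac = q * (1.0 - q)
    dlogits = np.empty_like(logits, dtype=np.float64)
    dlogits[:, 1] = dq * jac
    dlogits[:, 0] = -dq * jac
    return float(losses.mean()), dlogits.astype(logits.dtype)


# --------------------------------------------------------------------- scores

@dataclass
class ConfusionCounts:
    """Pixel-level TP/FP/TN/FN tallies; TP = vessel predicted vessel."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    bad = np.setdiff1d(np.unique(a), (0, 1))
    if bad.size:
        raise MetricError(f"{name} must be binary; found values {bad.tolist()}")
    return a.astype(bool)


def confusion_counts(pred_mask: np.ndarray, truth_mask: np.ndarray,
                     region: Optional[np.ndarray] = None) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over all pixels (or over ``region`` if given)."""
    pred = _check_binary(pred_mask, "pred_mask")
    truth = _check_binary(truth_mask, "truth_mask")
    if pred.shape != truth.shape:
        raise MetricError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if region is not None:
        sel = _check_binary(region, "region")
        pred, truth = pred[sel], truth[sel]
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """SE (true positive rate): TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise MetricError("sensitivity undefined: no vessel pixels in truth")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """SP (true negative rate): TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise MetricError("specificity undefined: no background pixels in truth")
    return c.tn / (c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """Acc: (TP + TN) / (TP + FN + FP + TN)."""
    if c.total == 0:
        raise MetricError("accuracy undefined: no pixels evaluated")
    return (c.tp + c.tn) / c.total


def roc_auc(pred_probs: np.ndarray, truth_mask: np.ndarray) -> float:
    """Area under the ROC curve over pixel probabilities.

    Equals the Mann-Whitney probability that a random vessel pixel outscores
    a random background pixel, with ties counting one half.
    """
    truth = _check_binary(truth_mask, "truth_mask").ravel()
    probs = np.asarray(pred_probs, dtype=np.float64).ravel()
    if truth.all() or not truth.any():
        raise MetricError("roc_auc undefined: truth contains a single class")
    return float(roc_auc_score(truth.astype(int), probs))


@dataclass
class SegmentationScores:
    se: float
    sp: float
    acc: float
    auc: float


def score_image(pred_probs: np.ndarray, truth_mask: np.ndarray,
                threshold: float = 0.5,
                region: Optional[np.ndarray] = None) -> tuple[ConfusionCounts,
                                                              SegmentationScores]:
    """All four statistics for one image from the vessel probability map."""
    pred = (np.asarray(pred_probs) >= threshold).astype(np.uint8)
    c = confusion_counts(pred, truth_mask, region=region)
    if region is not None:
        sel = np.asarray(region, dtype=bool)
        auc = roc_auc(np.asarray(pred_probs)[sel], np.asarray(truth_mask)[sel])
    else:
        auc = roc_auc(pred_probs, truth_mask)
    return c, SegmentationScores(se=sensitivity(c), sp=specificity(c),
                                 acc=accuracy(c), auc=auc)


def score_report(per_image: list[dict]) -> dict:
    """Assemble the JSON score report: per-image records plus micro (pooled
    pixel counts; the headline) and macro (mean of per-image scores)
    aggregates."""
    pooled = ConfusionCounts(
        tp=sum(r["tp"] for r in per_image),
        fp=sum(r["fp"] for r in per_image),
        tn=sum(r["tn"] for r in per_image),
        fn=sum(r["fn"] for r in per_image),
    )
    micro = {
        "se": sensitivity(pooled), "sp": specificity(pooled),
        "acc": accuracy(pooled),
        "auc": float(np.mean([r["auc"] for r in per_image])),
    }
    macro = {k: float(np.mean([r[k] for r in per_image]))
             for k in ("se", "sp", "acc", "auc")}
    return {"per_image": per_image, "micro": micro, "macro": macro}
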