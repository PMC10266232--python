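"""Box-level detection evaluation: IoU, greedy matching, precision/recall, AP.

Single-class evaluation.  Boxes are half-open pixel rectangles
(xmin, ymin, xmax, ymax); predictions carry confidences.  Matching is the
standard greedy protocol: predictions in descending confidence, each taking
the unmatched ground truth with the highest IoU at or above the threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "MatchCounts",
    "augmented_count",
    "iou",
    "match_detections",
    "precision",
    "recall",
    "average_precision",
    "mean_average_precision",
    "format_percent",
]


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def augmented_count(n_original: int, n_augmentations_per_image: int = 3) -> int:
    """Dataset size after augmentation: originals plus k variants of each."""
    if n_original < 0 or n_augmentations_per_image < 0:
        raise ValueError("counts must be non-negative")
    return n_original * (1 + n_augmentations_per_image)


def _box(b) -> tuple[float, float, float, float]:
    if hasattr(b, "xmin"):
        return (b.xmin, b.ymin, b.xmax, b.ymax)
    return tuple(b)


def iou(a, b) -> float:
    """Intersection over union of two half-open boxes, in [0, 1]."""
    ax0, ay0, ax1, ay1 = _box(a)
    bx0, by0, bx1, by1 = _box(b)
    area_a = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    area_b = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if area_a == 0.0 or area_b == 0.0:
        warnings.warn("zero-area box in IoU")
        return 0.0
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def _iou_matrix(pred_boxes: np.ndarray, gt_boxes: np.ndarray) -> np.ndarray:
    """Pairwise IoU, (n_pred, n_gt); zero-area boxes yield zero rows/cols."""
    px0, py0, px1, py1 = (pred_boxes[:, k][:, None] for k in range(4))
    gx0, gy0, gx1, gy1 = (gt_boxes[:, k][None, :] for k in range(4))
    iw = np.minimum(px1, gx1) - np.maximum(px0, gx0)
    ih = np.minimum(py1, gy1) - np.maximum(py0, gy0)
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_p = np.clip(px1 - px0, 0, None) * np.clip(py1 - py0, 0, None)
    area_g = np.clip(gx1 - gx0, 0, None) * np.clip(gy1 - gy0, 0, None)
    union = area_p + area_g - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def _match_flags(preds, gts, iou_threshold: float) -> np.ndarray:
    """Per-prediction TP flags, predictions taken in descending confidence."""
    if len(preds) == 0 or len(gts) == 0:
        return np.zeros(len(preds), dtype=bool)
    pb = np.array([_box(_pred_box(p)) for p in preds], dtype=float)
    gb = np.array([_box(g) for g in gts], dtype=float)
    m = _iou_matrix(pb, gb)
    order = sorted(range(len(preds)), key=lambda i: -_conf(preds[i]))
    free = np.ones(len(gts), dtype=bool)
    flags = np.zeros(len(preds), dtype=bool)
    for i in order:
        row = np.where(free, m[i], -1.0)
        j = int(np.argmax(row))
        if row[j] >= iou_threshold and row[j] > 0:
            free[j] = False
            flags[i] = True
    return flags


def _conf(p) -> float:
    return p.confidence if hasattr(p, "confidence") else float(p[1])


def _pred_box(p):
    if hasattr(p, "xmin"):
        return p
    return p[0]


def match_detections(preds, gts, iou_threshold: float = 0.5) -> MatchCounts:
    """Greedy confidence-ordered matching; returns TP/FP/FN counts.

    ``preds`` is a sequence of (box, confidence) pairs (or objects with
    .xmin.. and .confidence); ``gts`` a sequence of boxes.
    """
    flags = _match_flags(preds, gts, iou_threshold)
    tp = int(flags.sum())
    counts = MatchCounts(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp)
    assert counts.tp + counts.fn == len(gts)
    assert counts.tp + counts.fp == len(preds)
    return counts


def precision(c: MatchCounts) -> float:
    """100 * TP / (TP + FP); raises on an empty prediction set."""
    if c.tp + c.fp == 0:
        raise ZeroDivisionError("precision undefined: no predictions (TP + FP = 0)")
    return 100.0 * c.tp / (c.tp + c.fp)


def recall(c: MatchCounts) -> float:
    """100 * TP / (TP + FN); raises on an empty ground-truth set."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("recall undefined: no ground truth (TP + FN = 0)")
    return 100.0 * c.tp / (c.tp + c.fn)


def format_percent(value: float) -> str:
    """Round-half-up to one decimal for display (97.25 -> '97.3')."""
    return str(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def average_precision(preds, gts, iou_threshold: float = 0.5) -> float:
    """All-point interpolated AP (%) at one IoU threshold.

    Area under the monotone (non-increasing) envelope of the
    precision-recall staircase traced by descending-confidence predictions.
    """
    if len(gts) == 0:
        raise ValueError("AP undefined with no ground-truth boxes")
    if len(preds) == 0:
        return 0.0
    flags = _match_flags(preds, gts, iou_threshold)
    order = np.argsort([-_conf(p) for p in preds], kind="stable")
    tp_cum = np.cumsum(flags[order])
    k = np.arange(1, len(preds) + 1)
    prec = tp_cum / k
    rec = tp_cum / len(gts)
    # monotone envelope from the right, then integrate over recall jumps
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    rec_prev = np.concatenate([[0.0], rec[:-1]])
    ap = float(np.sum((rec - rec_prev) * prec_env))
    return 100.0 * ap


def mean_average_precision(preds, gts, thresholds=(0.5,)) -> float:
    """Mean of AP over IoU thresholds (e.g. 0.5:0.95 in steps of 0.05), %."""
    if np.isscalar(thresholds):
        thresholds = (thresholds,)
    return float(np.mean([average_precision(preds, gts, t) for t in thresholds]))
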