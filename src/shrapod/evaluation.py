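"""Detection evaluation: IoU, TP/FP/FN matching, PR curves, AP and mIoU.

The protocol gates correctness on box IoU at a fixed threshold
(default 0.5).  Within one image and one class, predictions are matched
greedily in descending confidence: a prediction claims the unmatched
ground truth with which it has the highest IoU, provided that IoU meets
the threshold (a true positive).  Every remaining prediction — whether
it overlaps nothing or is a surplus prediction on an already-claimed
ground truth — is a false positive, and every unclaimed ground truth is
a false negative.

The per-class mean IoU (mIoU) is taken over an image-level IoU sample
that includes zeros: an image with a ground truth but no (overlapping)
prediction contributes 0, as does a spurious prediction on an image
with no ground truth of that class.  Images where the class is entirely
absent (no truth, no prediction) do not enter the distribution.

Average precision is the area under the precision-recall curve built
from the pooled, confidence-ranked detections of a class, by default
with the all-point "precision envelope" interpolation; a raw trapezoid
rule is available via ``interpolation="trapezoid"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .boxes import CLASSES, BBox, Detection

__all__ = [
    "iou",
    "match_image",
    "pr_curve_and_ap",
    "summarize_class",
    "summarize_all",
    "evaluate_dataset",
    "MatchResult",
    "ClassSummary",
    "PRCurve",
]


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes, in ``[0, 1]``.

    Raises
    ------
    ValueError
        If both boxes have zero area (the union is empty and the ratio
        is undefined).
    """
    union_base = a.area + b.area
    if union_base == 0.0:
        raise ValueError("IoU undefined: both boxes have zero area")
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    inter = max(ix, 0.0) * max(iy, 0.0)
    # clamp rounding noise at the extremes
    return min(max(inter / (union_base - inter), 0.0), 1.0)


@dataclass
class MatchResult:
    """TP/FP/FN counts and IoU samples for one image and one class."""

    tp: int
    fp: int
    fn: int
    #: Best IoU achieved against each ground truth (0 if no prediction
    #: overlaps it); one entry per ground truth, in input order.
    gt_best_ious: list[float]
    #: Image-level IoU sample for the mIoU distribution: the mean of
    #: ``gt_best_ious`` when ground truths are present, 0.0 when only
    #: predictions are present, ``None`` when the class is absent from
    #: both (the image then drops out of the distribution).
    image_iou: float | None
    #: Index of the matched ground truth per prediction (confidence
    #: order), -1 for false positives.
    assignment: list[int] = field(default_factory=list)


def _sorted_by_confidence(preds: Sequence[Detection]) -> list[Detection]:
    # Stable sort: descending confidence, larger area first on ties.
    return sorted(
        preds, key=lambda d: (-d.confidence, -d.box.area)
    )


def match_image(
    preds: Sequence[Detection],
    truths: Sequence[BBox],
    iou_min: float = 0.5,
) -> MatchResult:
    """Match single-class predictions to ground truths in one image.

    Raises
    ------
    ValueError
        If the predictions and truths do not share a single class label.
    """
    labels = {d.box.label for d in preds} | {t.label for t in truths}
    if len(labels) > 1:
        raise ValueError(f"match_image expects a single class, got {sorted(labels)}")

    order = _sorted_by_confidence(preds)
    matched: set[int] = set()
    assignment: list[int] = []
    tp = 0
    for det in order:
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truths):
            if j in matched:
                continue
            try:
                v = iou(det.box, t)
            except ValueError:
                v = 0.0
            if v > best_iou or (v == best_iou and v > 0 and best_j == -1):
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_min:
            matched.add(best_j)
            assignment.append(best_j)
            tp += 1
        else:
            assignment.append(-1)

    fp = len(preds) - tp
    fn = len(truths) - tp

    gt_best: list[float] = []
    for t in truths:
        best = 0.0
        for det in order:
            try:
                best = max(best, iou(det.box, t))
            except ValueError:
                pass
        gt_best.append(best)

    if truths:
        image_iou: float | None = float(np.mean(gt_best))
    elif preds:
        image_iou = 0.0
    else:
        image_iou = None

    return MatchResult(tp=tp, fp=fp, fn=fn, gt_best_ious=gt_best,
                       image_iou=image_iou, assignment=assignment)


@dataclass
class PRCurve:
    """Cumulative precision/recall at each pooled detection."""

    confidence: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"confidence": self.confidence, "precision": self.precision,
             "recall": self.recall}
        )


def pr_curve_and_ap(
    preds_by_image: Sequence[Sequence[Detection]],
    truths_by_image: Sequence[Sequence[BBox]],
    iou_min: float = 0.5,
    interpolation: str = "envelope",
) -> tuple[PRCurve, float]:
    """Precision-recall curve and average precision for one class.

    Detections are pooled over all images and ranked by descending
    confidence; each is a TP if it claims a so-far-unclaimed ground
    truth in its image at IoU >= ``iou_min``, else an FP.

    Raises
    ------
    ValueError
        If there are no ground truths for the class (AP undefined).
    """
    if len(preds_by_image) != len(truths_by_image):
        raise ValueError("preds_by_image and truths_by_image lengths differ")
    n_truth = sum(len(t) for t in truths_by_image)
    if n_truth == 0:
        raise ValueError("AP undefined with zero ground truths")

    pooled: list[tuple[float, int, Detection]] = []
    for i, preds in enumerate(preds_by_image):
        for det in _sorted_by_confidence(preds):
            pooled.append((det.confidence, i, det))
    pooled.sort(key=lambda t: (-t[0], -t[2].box.area))

    matched: list[set[int]] = [set() for _ in truths_by_image]
    tp_flags = np.zeros(len(pooled), dtype=bool)
    for k, (_, i, det) in enumerate(pooled):
        truths = truths_by_image[i]
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truths):
            if j in matched[i]:
                continue
            try:
                v = iou(det.box, t)
            except ValueError:
                v = 0.0
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_min:
            matched[i].add(best_j)
            tp_flags[k] = True

    conf = np.array([c for c, _, _ in pooled], dtype=float)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    n_det = np.arange(1, len(pooled) + 1)
    precision = tp_cum / n_det if len(pooled) else np.array([])
    recall = tp_cum / n_truth if len(pooled) else np.array([])
    curve = PRCurve(confidence=conf, precision=precision, recall=recall)
    return curve, _area_under_pr(precision, recall, interpolation)


def _area_under_pr(precision: np.ndarray, recall: np.ndarray,
                   interpolation: str) -> float:
    if len(recall) == 0:
        return 0.0
    if interpolation == "envelope":
        # All-point interpolation: precision envelope summed over recall
        # increments (VOC-2010 convention).
        r = np.concatenate([[0.0], recall, [recall[-1]]])
        p = np.concatenate([[0.0], precision, [0.0]])
        for k in range(len(p) - 2, -1, -1):
            p[k] = max(p[k], p[k + 1])
        idx = np.where(r[1:] != r[:-1])[0]
        return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    if interpolation == "trapezoid":
        r = np.concatenate([[0.0], recall])
        p = np.concatenate([[precision[0] if len(precision) else 0.0], precision])
        return float(np.trapezoid(p, r))
    raise ValueError(f"unknown interpolation {interpolation!r}")


@dataclass
class ClassSummary:
    """Per-class summary row: percent TP/FP/FN, mIoU, P/R/F1 and AP.

    Percent columns are fractions of all decision events for the class
    (TP + FP + FN), expressed in percent, so each row sums to ~100.
    Ratios undefined for the data (0/0) are ``None`` and are excluded
    from cross-class averages.
    """

    pct_tp: float | None
    pct_fp: float | None
    pct_fn: float | None
    miou: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    ap: float | None

    COLUMNS = ("pct_tp", "pct_fp", "pct_fn", "miou", "precision",
               "recall", "f1", "ap")

    def as_dict(self) -> dict[str, float | None]:
        return {c: getattr(self, c) for c in self.COLUMNS}


def f1_score(precision: float, recall: float) -> float | None:
    """Harmonic mean of precision and recall; ``None`` when both are 0."""
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def summarize_class(matches: Iterable[MatchResult], ap: float | None) -> ClassSummary:
    """Aggregate per-image match results into one summary row."""
    matches = list(matches)
    tp = sum(m.tp for m in matches)
    fp = sum(m.fp for m in matches)
    fn = sum(m.fn for m in matches)

    total = tp + fp + fn
    pct = (lambda c: 100.0 * c / total) if total else (lambda c: None)
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f1 = f1_score(precision, recall) if precision is not None and recall is not None else None

    samples = [m.image_iou for m in matches if m.image_iou is not None]
    miou = float(np.mean(samples)) if samples else None

    return ClassSummary(
        pct_tp=pct(tp), pct_fp=pct(fp), pct_fn=pct(fn), miou=miou,
        precision=precision, recall=recall, f1=f1, ap=ap,
    )


def summarize_all(per_class: dict[str, ClassSummary]) -> ClassSummary:
    """Unweighted column-wise mean across classes (mAP, average mIoU, ...).

    ``None`` entries (undefined ratios) are excluded column by column.
    """
    if not per_class:
        raise ValueError("need at least one class summary")
    values: dict[str, float | None] = {}
    for col in ClassSummary.COLUMNS:
        xs = [getattr(s, col) for s in per_class.values()
              if getattr(s, col) is not None]
        values[col] = float(np.mean(xs)) if xs else None
    return ClassSummary(**values)


def evaluate_dataset(
    preds_by_image: Sequence[Sequence[Detection]],
    truths_by_image: Sequence[Sequence[BBox]],
    classes: Sequence[str] = CLASSES,
    iou_min: float = 0.5,
    interpolation: str = "envelope",
) -> tuple[pd.DataFrame, dict[str, ClassSummary], dict[str, PRCurve]]:
    """Full multi-class evaluation over a test set.

    Returns the summary as a DataFrame (one column per class plus an
    ``average`` column, one row per metric), the per-class summaries,
    and the per-class PR curves.
    """
    summaries: dict[str, ClassSummary] = {}
    curves: dict[str, PRCurve] = {}
    for cls in classes:
        cls_preds = [[d for d in preds if d.box.label == cls]
                     for preds in preds_by_image]
        cls_truths = [[t for t in truths if t.label == cls]
                      for truths in truths_by_image]
        matches = [match_image(p, t, iou_min)
                   for p, t in zip(cls_preds, cls_truths)]
        if sum(len(t) for t in cls_truths) > 0:
            curves[cls], ap = pr_curve_and_ap(
                cls_preds, cls_truths, iou_min, interpolation)
        else:
            ap = None
        summaries[cls] = summarize_class(matches, ap)

    table = pd.DataFrame(
        {cls: s.as_dict() for cls, s in summaries.items()}
    )
    table["average"] = pd.Series(summarize_all(summaries).as_dict())
    return table, summaries, curves
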