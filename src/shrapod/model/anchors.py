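"""Anchor-box estimation by k-means clustering in (width, height) space.

The distance between a box shape and an anchor is ``1 − IoU`` of the
two rectangles placed at a common centre, so clustering optimises how
well anchors fit the training-box shapes irrespective of position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..boxes import BBox

__all__ = ["AnchorSet", "estimate_anchors", "mean_best_iou", "shape_iou"]


def shape_iou(wh_a: np.ndarray, wh_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of centre-aligned rectangles.

    ``wh_a``: (n, 2), ``wh_b``: (m, 2) → (n, m).
    """
    wa, ha = wh_a[:, 0][:, None], wh_a[:, 1][:, None]
    wb, hb = wh_b[:, 0][None, :], wh_b[:, 1][None, :]
    inter = np.minimum(wa, wb) * np.minimum(ha, hb)
    union = wa * ha + wb * hb - inter
    return inter / np.maximum(union, 1e-12)


@dataclass(frozen=True)
class AnchorSet:
    """(w, h) anchor priors partitioned between the two detection heads.

    Anchors are stored sorted by descending area; the coarse (stride 32)
    head takes the larger ``n_coarse`` anchors, the fine (stride 16)
    head the rest.
    """

    anchors: tuple[tuple[float, float], ...]
    n_coarse: int

    def __post_init__(self) -> None:
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise ValueError("anchor dimensions must be positive")
        if not 0 < self.n_coarse <= len(self.anchors):
            raise ValueError("invalid coarse/fine anchor partition")

    @property
    def k(self) -> int:
        return len(self.anchors)

    @property
    def coarse(self) -> tuple[tuple[float, float], ...]:
        return self.anchors[: self.n_coarse]

    @property
    def fine(self) -> tuple[tuple[float, float], ...]:
        return self.anchors[self.n_coarse:]

    def per_head(self) -> tuple[tuple[tuple[float, float], ...], ...]:
        return (self.coarse, self.fine)

    @classmethod
    def from_wh(cls, wh: np.ndarray, n_coarse: int | None = None) -> "AnchorSet":
        order = np.argsort(-(wh[:, 0] * wh[:, 1]))
        wh = wh[order]
        if n_coarse is None:
            # 23 anchors split 12 coarse / 11 fine; generalised as the
            # larger half to the coarse head.
            n_coarse = (len(wh) + 1) // 2
        return cls(tuple((float(w), float(h)) for w, h in wh), n_coarse)


def estimate_anchors(boxes: Sequence[BBox], k: int = 23,
                     seed: int = 0, max_iter: int = 100,
                     n_coarse: int | None = None,
                     objective_history: list[float] | None = None) -> AnchorSet:
    """Cluster training-box shapes into ``k`` anchors (1 − IoU k-means).

    Deterministic for a fixed seed (k-means++ style initialisation).
    The mean 1 − IoU objective is evaluated every iteration and the
    update stops as soon as it would increase, so the objective is
    non-increasing across accepted iterations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    wh = np.array([[b.w, b.h] for b in boxes], dtype=float)
    if len(wh) < k:
        raise ValueError(f"need at least {k} boxes, got {len(wh)}")
    distinct = np.unique(wh, axis=0)
    if len(distinct) < k:
        raise ValueError(
            f"k={k} exceeds the {len(distinct)} distinct (w, h) shapes")

    rng = np.random.default_rng(seed)

    # k-means++ seeding with the 1 - IoU distance.
    centers = [distinct[rng.integers(len(distinct))]]
    while len(centers) < k:
        d = 1.0 - shape_iou(distinct, np.array(centers)).max(axis=1)
        probs = d / d.sum() if d.sum() > 0 else np.full(len(distinct), 1 / len(distinct))
        centers.append(distinct[rng.choice(len(distinct), p=probs)])
    centers = np.array(centers, dtype=float)

    def objective(c: np.ndarray) -> float:
        return float((1.0 - shape_iou(wh, c).max(axis=1)).mean())

    best_obj = objective(centers)
    if objective_history is not None:
        objective_history.append(best_obj)
    for _ in range(max_iter):
        assign = shape_iou(wh, centers).argmax(axis=1)
        new = centers.copy()
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                new[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster to the worst-fit box
                d = 1.0 - shape_iou(wh, new).max(axis=1)
                new[j] = wh[d.argmax()]
        new_obj = objective(new)
        if new_obj > best_obj + 1e-12:
            break
        improved = best_obj - new_obj > 1e-9
        centers, best_obj = new, new_obj
        if objective_history is not None:
            objective_history.append(best_obj)
        if not improved:
            break

    return AnchorSet.from_wh(centers, n_coarse=n_coarse)


def mean_best_iou(boxes: Sequence[BBox], anchors: AnchorSet) -> float:
    """Mean over boxes of the best centre-aligned IoU with any anchor."""
    wh = np.array([[b.w, b.h] for b in boxes], dtype=float)
    a = np.array(anchors.anchors, dtype=float)
    return float(shape_iou(wh, a).max(axis=1).mean())
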