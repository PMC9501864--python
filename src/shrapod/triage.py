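"""Shrapnel-proximity triage metric.

For every image in which the detector produced all four classes
(shrapnel, vein, artery, nerve), the metric takes the single
highest-confidence detection per class, computes the Euclidean distance
between the shrapnel box midpoint and each neurovascular feature's box
midpoint, and reports the minimum of the three as the per-image triage
distance.  Images whose triage distance falls below a multiple of a
reference length — the average artery box size in the ground truth —
are flagged as potentially needing urgent intervention.

Distances are in pixels; an optional ``px_per_mm`` scale converts the
report to millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boxes import NEUROVASCULAR, BBox, Detection

__all__ = [
    "Midpoint",
    "TriageRecord",
    "TriageSummary",
    "midpoint",
    "pair_distance",
    "triage_image",
    "reference_diameter",
    "gate",
    "DEFAULT_MULTIPLIERS",
]

#: Gate multipliers of the reference artery diameter.
DEFAULT_MULTIPLIERS: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)

#: Tie-break priority when two features are equidistant: most critical first.
_TIE_ORDER = ("artery", "nerve", "vein")


@dataclass(frozen=True)
class Midpoint:
    mx: float
    my: float


def midpoint(box: BBox) -> Midpoint:
    """Box midpoint ``(x + w/2, y + h/2)``; fractional values preserved."""
    return Midpoint(box.x + box.w / 2.0, box.y + box.h / 2.0)


def pair_distance(p: Midpoint, q: Midpoint) -> float:
    """Euclidean distance between two midpoints, in pixels."""
    return math.hypot(q.mx - p.mx, q.my - p.my)


@dataclass
class TriageRecord:
    """Per-image shrapnel-to-feature distances and gate flags."""

    image_id: int | str
    d_vein: float
    d_artery: float
    d_nerve: float
    d_min: float
    closest: str
    flags: dict[float, bool] = field(default_factory=dict)

    def distance(self, feature: str) -> float:
        return {"vein": self.d_vein, "artery": self.d_artery,
                "nerve": self.d_nerve}[feature]


def _best_per_class(dets: Sequence[Detection]) -> dict[str, Detection]:
    """Highest-confidence detection per class.

    Confidence ties are broken by larger box area, then first-seen order.
    """
    best: dict[str, Detection] = {}
    for det in dets:
        cur = best.get(det.label)
        if cur is None or (det.confidence, det.box.area) > (cur.confidence, cur.box.area):
            best[det.label] = det
    return best


def triage_image(dets: Sequence[Detection],
                 image_id: int | str = 0) -> TriageRecord | None:
    """Triage one image's detections, or ``None`` if it is filtered out.

    An image enters the triage population only when detections for all
    four classes are present; otherwise the image is skipped entirely.
    """
    best = _best_per_class(dets)
    if any(cls not in best for cls in ("shrapnel",) + NEUROVASCULAR):
        return None

    sp = midpoint(best["shrapnel"].box)
    dists = {f: pair_distance(midpoint(best[f].box), sp) for f in NEUROVASCULAR}
    d_min = min(dists.values())
    closest = next(f for f in _TIE_ORDER if dists[f] == d_min)
    return TriageRecord(
        image_id=image_id, d_vein=dists["vein"], d_artery=dists["artery"],
        d_nerve=dists["nerve"], d_min=d_min, closest=closest,
    )


def reference_diameter(artery_truths: Iterable[BBox]) -> float:
    """Average artery ground-truth window size: mean of per-box (w + h)/2."""
    sizes = [(b.w + b.h) / 2.0 for b in artery_truths]
    if not sizes:
        raise ValueError("reference diameter needs at least one artery box")
    return float(np.mean(sizes))


@dataclass
class TriageSummary:
    """Distance statistics and gated flag fractions over a record set."""

    n_images: int
    mean_d_min: float | None
    #: feature -> {"mean": .., "max": .., "min": ..} distances in px.
    feature_stats: dict[str, dict[str, float]]
    #: feature -> percent of records for which it was the closest.
    closest_frequency: dict[str, float]
    #: multiplier -> percent of records with d_min < multiplier × reference.
    flagged_pct: dict[float, float]
    reference_diameter: float

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "mean_distance": {f: s["mean"] for f, s in self.feature_stats.items()},
            "max_distance": {f: s["max"] for f, s in self.feature_stats.items()},
            "min_distance": {f: s["min"] for f, s in self.feature_stats.items()},
            "closest_frequency_pct": dict(self.closest_frequency),
        }
        return pd.DataFrame(rows).T


def gate(records: Sequence[TriageRecord], reference: float,
         multipliers: Sequence[float] = DEFAULT_MULTIPLIERS) -> TriageSummary:
    """Gate triage distances against multiples of the reference diameter.

    A record is flagged at multiplier ``m`` iff ``d_min < m * reference``
    (strict: boundary equality is not flagged).  Flags are also written
    back onto each record.
    """
    if reference <= 0:
        raise ValueError("reference diameter must be positive")
    n = len(records)
    if n == 0:
        return TriageSummary(
            n_images=0, mean_d_min=None, feature_stats={},
            closest_frequency={}, flagged_pct={m: 0.0 for m in multipliers},
            reference_diameter=reference,
        )

    d_min = np.array([r.d_min for r in records], dtype=float)
    flagged: dict[float, float] = {}
    for m in multipliers:
        hits = d_min < m * reference
        flagged[m] = 100.0 * float(np.mean(hits))
        for r, hit in zip(records, hits):
            r.flags[m] = bool(hit)

    stats: dict[str, dict[str, float]] = {}
    freq: dict[str, float] = {}
    for f in NEUROVASCULAR:
        d = np.array([r.distance(f) for r in records], dtype=float)
        stats[f] = {"mean": float(d.mean()), "max": float(d.max()),
                    "min": float(d.min())}
        freq[f] = 100.0 * sum(r.closest == f for r in records) / n

    return TriageSummary(
        n_images=n, mean_d_min=float(d_min.mean()), feature_stats=stats,
        closest_frequency=freq, flagged_pct=flagged,
        reference_diameter=reference,
    )
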