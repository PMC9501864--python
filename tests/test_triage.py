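"""Tests for the shrapnel-proximity triage metric and gating."""

from __future__ import annotations

import math

import numpy as np
import pytest

from shrapod import BBox, Detection
from shrapod.triage import (DEFAULT_MULTIPLIERS, TriageRecord, gate, midpoint,
                            pair_distance, reference_diameter, triage_image)


def det(x, y, w, h, conf=0.9, label="shrapnel"):
    return Detection(BBox(x, y, w, h, label), conf)


@pytest.mark.parametrize(
    "box, expected",
    [
        (BBox(10, 20, 30, 40), (25.0, 40.0)),
        (BBox(0, 0, 0, 0), (0.0, 0.0)),
        (BBox(100, 100, 51, 51), (125.5, 125.5)),  # fractional preserved
    ],
)
def test_midpoint(box, expected):
    m = midpoint(box)
    assert (m.mx, m.my) == expected


@pytest.mark.parametrize(
    "p, q, expected",
    [
        ((0, 0), (3, 4), 5.0),
        ((2, 7), (2, 7), 0.0),
        ((1, 1), (4, 5), 5.0),
    ],
)
def test_pair_distance(p, q, expected):
    from shrapod.triage import Midpoint

    assert pair_distance(Midpoint(*p), Midpoint(*q)) == pytest.approx(expected)


def four_class_detections():
    """Shrapnel at (0,0,10,10); vein/artery/nerve mids at (30,40)/(60,80)/(6,13)."""
    return [
        det(0, 0, 10, 10, 0.9, "shrapnel"),
        det(25, 35, 10, 10, 0.8, "vein"),
        det(55, 75, 10, 10, 0.8, "artery"),
        det(1, 8, 10, 10, 0.8, "nerve"),
    ]


class TestTriageImage:
    def test_hand_computed_distances_and_closest(self):
        rec = triage_image(four_class_detections(), image_id=5)
        assert rec.d_vein == pytest.approx(math.hypot(25, 35), abs=5e-3)
        assert rec.d_artery == pytest.approx(math.hypot(55, 75), abs=5e-3)
        assert rec.d_nerve == pytest.approx(math.hypot(1, 8), abs=5e-3)
        assert rec.d_min == rec.d_nerve
        assert rec.closest == "nerve"
        assert rec.d_min <= min(rec.d_vein, rec.d_artery)

    def test_image_without_all_four_classes_is_filtered(self):
        dets = [d for d in four_class_detections() if d.label != "nerve"]
        assert triage_image(dets) is None
        assert triage_image([]) is None

    def test_highest_confidence_prediction_wins(self):
        dets = four_class_detections() + [det(100, 100, 10, 10, 0.6, "shrapnel")]
        rec = triage_image(dets)
        # the 0.9 shrapnel at (5, 5) is used, not the 0.6 one at (105, 105)
        assert rec.d_nerve == pytest.approx(math.hypot(1, 8), abs=5e-3)

    def test_confidence_tie_broken_by_larger_area(self):
        dets = four_class_detections() + [det(100, 100, 40, 40, 0.9, "shrapnel")]
        rec = triage_image(dets)
        assert rec.d_nerve == pytest.approx(
            math.hypot(120 - 6, 120 - 13), abs=5e-3)

    def test_translation_and_scale_equivariance(self):
        base = triage_image(four_class_detections())
        moved = triage_image([Detection(d.box.translate(17, -3), d.confidence)
                              for d in four_class_detections()])
        assert moved.d_min == pytest.approx(base.d_min)
        scaled = triage_image([Detection(d.box.scale(2.0), d.confidence)
                               for d in four_class_detections()])
        assert scaled.d_min == pytest.approx(2.0 * base.d_min)
        assert scaled.closest == base.closest


class TestReferenceDiameter:
    def test_constant_boxes(self):
        assert reference_diameter([BBox(0, 0, 75, 75, "artery")] * 3) == 75.0

    def test_mean_of_square_boxes(self):
        boxes = [BBox(0, 0, 70, 70, "artery"), BBox(0, 0, 80, 80, "artery")]
        assert reference_diameter(boxes) == 75.0

    def test_mean_of_wh_average(self):
        boxes = [BBox(0, 0, 60, 80, "artery"), BBox(0, 0, 80, 100, "artery")]
        assert reference_diameter(boxes) == 80.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            reference_diameter([])


def records_with_dmin(values):
    return [TriageRecord(i, d + 10, d + 20, d, d, "nerve")
            for i, d in enumerate(values)]


class TestGate:
    def test_counting_below_threshold(self):
        s = gate(records_with_dmin([30, 60, 90, 120]), reference=75.0,
                 multipliers=(1.0,))
        assert s.flagged_pct[1.0] == pytest.approx(50.0)

    def test_all_zero_distances_flag_everywhere(self):
        s = gate(records_with_dmin([0, 0, 0]), reference=75.0)
        assert all(v == 100.0 for v in s.flagged_pct.values())

    def test_tiny_reference_flags_nothing(self):
        s = gate(records_with_dmin([30, 60]), reference=1.0)
        assert all(v == 0.0 for v in s.flagged_pct.values())

    def test_strict_comparison_at_boundary(self):
        s = gate(records_with_dmin([75.0]), reference=75.0, multipliers=(1.0,))
        assert s.flagged_pct[1.0] == 0.0

    def test_flagged_fraction_monotone_in_multiplier(self):
        rng = np.random.default_rng(3)
        recs = records_with_dmin(rng.uniform(5, 200, size=60))
        s = gate(recs, reference=75.0)
        vals = [s.flagged_pct[m] for m in DEFAULT_MULTIPLIERS]
        assert vals == sorted(vals)

    def test_closest_frequencies_sum_to_hundred(self):
        rng = np.random.default_rng(4)
        recs = []
        for i in range(50):
            d = dict(d_vein=float(rng.uniform(10, 100)),
                     d_artery=float(rng.uniform(10, 100)),
                     d_nerve=float(rng.uniform(10, 100)))
            dmin = min(d.values())
            closest = [f for f in ("artery", "nerve", "vein")
                       if d[f"d_{f}"] == dmin][0]
            recs.append(TriageRecord(i, d_min=dmin, closest=closest, **d))
        s = gate(recs, reference=75.0)
        assert sum(s.closest_frequency.values()) == pytest.approx(100.0)

    def test_empty_records_give_empty_summary(self):
        s = gate([], reference=75.0)
        assert s.n_images == 0 and s.mean_d_min is None

    def test_flags_written_back_to_records(self):
        recs = records_with_dmin([10.0])
        gate(recs, reference=75.0, multipliers=(0.5, 1.0))
        assert recs[0].flags == {0.5: True, 1.0: True}
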