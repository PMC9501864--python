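"""Unit and property tests for IoU, matching, PR/AP and summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shrapod import BBox, Detection
from shrapod.evaluation import (ClassSummary, evaluate_dataset, f1_score, iou,
                                match_image, pr_curve_and_ap, summarize_all,
                                summarize_class)

# --- independent oracles -----------------------------------------------------


def shapely_iou(a: BBox, b: BBox) -> float:
    """Polygon-based IoU, independent of the arithmetic implementation."""
    from shapely.geometry import box as shp_box

    pa = shp_box(a.x, a.y, a.x2, a.y2)
    pb = shp_box(b.x, b.y, b.x2, b.y2)
    union = pa.union(pb).area
    return pa.intersection(pb).area / union


def boxes_strategy(label="shrapnel"):
    coord = st.floats(-50, 150, allow_nan=False, allow_infinity=False)
    size = st.floats(1, 80, allow_nan=False, allow_infinity=False)
    return st.builds(BBox, coord, coord, size, size, st.just(label))


# --- IoU ---------------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (BBox(3, 4, 10, 12), BBox(3, 4, 10, 12), 1.0),
        (BBox(0, 0, 10, 10), BBox(20, 20, 5, 5), 0.0),
        (BBox(0, 0, 10, 10), BBox(5, 0, 10, 10), 1.0 / 3.0),
    ],
)
def test_iou_known_values(a, b, expected):
    assert iou(a, b) == pytest.approx(expected, abs=1e-12)


def test_iou_undefined_for_two_degenerate_boxes():
    with pytest.raises(ValueError):
        iou(BBox(0, 0, 0, 0), BBox(1, 1, 0, 0))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(boxes_strategy(), boxes_strategy())
def test_iou_properties_and_polygon_oracle(a, b):
    v = iou(a, b)
    assert 0.0 <= v <= 1.0
    assert v == pytest.approx(iou(b, a), abs=1e-12)          # symmetry
    assert v == pytest.approx(shapely_iou(a, b), abs=1e-9)   # oracle
    # translation invariance and scale covariance
    assert iou(a.translate(7, -3), b.translate(7, -3)) == pytest.approx(v, rel=1e-9)
    assert iou(a.scale(2.5), b.scale(2.5)) == pytest.approx(v, rel=1e-9)


def test_iou_is_one_only_for_identical_boxes():
    a = BBox(0, 0, 10, 10)
    assert iou(a, BBox(0, 0, 10, 10)) == 1.0
    assert iou(a, BBox(0.5, 0, 10, 10)) < 1.0


# --- matching ----------------------------------------------------------------


def det(x, y, w, h, conf=0.9, label="shrapnel"):
    return Detection(BBox(x, y, w, h, label), conf)


class TestMatchImage:
    def test_perfect_match(self):
        truths = [BBox(10, 10, 20, 20)]
        m = match_image([det(10, 10, 20, 20)], truths)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        assert m.image_iou == pytest.approx(1.0)

    def test_surplus_prediction_on_one_truth_is_false_positive(self):
        truths = [BBox(10, 10, 20, 20)]
        preds = [det(10, 10, 20, 20, 0.9), det(11, 11, 20, 20, 0.8)]
        m = match_image(preds, truths)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_prediction_without_truth_and_truth_without_prediction(self):
        m1 = match_image([det(0, 0, 10, 10)], [])
        assert (m1.tp, m1.fp, m1.fn) == (0, 1, 0)
        assert m1.image_iou == 0.0
        m2 = match_image([], [BBox(0, 0, 10, 10)])
        assert (m2.tp, m2.fp, m2.fn) == (0, 0, 1)
        assert m2.image_iou == 0.0

    def test_below_threshold_overlap_is_fp_and_fn(self):
        m = match_image([det(0, 0, 10, 10)], [BBox(8, 8, 10, 10)])
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)
        assert 0 < m.image_iou < 0.5

    def test_absent_class_yields_no_iou_sample(self):
        assert match_image([], []).image_iou is None

    def test_mixed_classes_rejected(self):
        with pytest.raises(ValueError):
            match_image([det(0, 0, 5, 5, label="vein")],
                        [BBox(0, 0, 5, 5, "artery")])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(boxes_strategy(),
                              st.floats(0.01, 1.0)), max_size=10),
           st.lists(boxes_strategy(), max_size=10))
    def test_count_conservation(self, scored, truths):
        preds = [Detection(b, c) for b, c in scored]
        m = match_image(preds, truths)
        assert m.tp + m.fp == len(preds)
        assert m.tp + m.fn == len(truths)
        assert len(m.gt_best_ious) == len(truths)


# --- PR curve and AP ---------------------------------------------------------


def ap_oracle(preds_by_image, truths_by_image, iou_min=0.5):
    """Exhaustive cut-point enumeration using match_image counts.

    For every prefix of the pooled confidence ranking, precision and
    recall are recomputed from scratch; the area is the precision
    envelope summed over recall increments.
    """
    pooled = sorted(
        ((d.confidence, i, d) for i, preds in enumerate(preds_by_image)
         for d in preds),
        key=lambda t: (-t[0], -t[2].box.area))
    n_truth = sum(len(t) for t in truths_by_image)
    points = []
    for k in range(1, len(pooled) + 1):
        kept = [[] for _ in preds_by_image]
        for _, i, d in pooled[:k]:
            kept[i].append(d)
        tp = sum(match_image(p, t, iou_min).tp
                 for p, t in zip(kept, truths_by_image))
        points.append((tp / k, tp / n_truth))
    area, prev_r = 0.0, 0.0
    for j, (p, r) in enumerate(points):
        if r > prev_r:
            env = max(q for q, s in points[j:] if s >= r)
            area += (r - prev_r) * env
            prev_r = r
    return area


def test_ap_perfect_detector_is_one():
    truths = [[BBox(0, 0, 10, 10)], [BBox(5, 5, 8, 8)]]
    preds = [[det(0, 0, 10, 10, 0.9)], [det(5, 5, 8, 8, 0.8)]]
    _, ap = pr_curve_and_ap(preds, truths)
    assert ap == pytest.approx(1.0)


def test_ap_no_predictions_is_zero():
    _, ap = pr_curve_and_ap([[]], [[BBox(0, 0, 10, 10)]])
    assert ap == 0.0


def test_ap_requires_ground_truths():
    with pytest.raises(ValueError):
        pr_curve_and_ap([[det(0, 0, 5, 5)]], [[]])


def test_ap_three_truth_hand_instance_matches_oracle():
    # predictions (conf, correct): (0.9, yes), (0.8, no), (0.7, yes)
    truths = [[BBox(0, 0, 10, 10), BBox(40, 40, 10, 10), BBox(80, 80, 10, 10)]]
    preds = [[det(0, 0, 10, 10, 0.9), det(200, 200, 10, 10, 0.8),
              det(40, 40, 10, 10, 0.7)]]
    curve, ap = pr_curve_and_ap(preds, truths)
    assert ap == pytest.approx(ap_oracle(preds, truths), abs=1e-12)
    assert ap == pytest.approx(1 / 3 + (1 / 3) * (2 / 3), abs=1e-12)
    np.testing.assert_allclose(curve.precision, [1.0, 0.5, 2 / 3])
    np.testing.assert_allclose(curve.recall, [1 / 3, 1 / 3, 2 / 3])


def test_ap_matches_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n_img = rng.integers(1, 4)
        truths, preds = [], []
        for _ in range(n_img):
            truths.append([BBox(*rng.uniform(0, 80, 2), *rng.uniform(5, 40, 2))
                           for _ in range(rng.integers(1, 4))])
            img_preds = []
            for t in truths[-1]:
                if rng.random() < 0.8:  # noisy copy of the truth
                    jitter = rng.normal(0, 4, 4)
                    img_preds.append(det(t.x + jitter[0], t.y + jitter[1],
                                         max(t.w + jitter[2], 2),
                                         max(t.h + jitter[3], 2),
                                         float(rng.uniform(0.1, 1.0))))
            for _ in range(rng.integers(0, 3)):  # clutter
                img_preds.append(det(*rng.uniform(0, 80, 2),
                                     *rng.uniform(5, 40, 2),
                                     float(rng.uniform(0.1, 1.0))))
            preds.append(img_preds[:10])
        if sum(len(t) for t in truths) == 0:
            continue
        _, ap = pr_curve_and_ap(preds, truths)
        assert ap == pytest.approx(ap_oracle(preds, truths), abs=1e-9)


# --- summaries ---------------------------------------------------------------


def make_matches(tp, fp, fn):
    """Synthesise per-image MatchResults with the requested totals."""
    from shrapod.evaluation import MatchResult

    out = []
    for _ in range(tp):
        out.append(MatchResult(1, 0, 0, [1.0], 1.0))
    for _ in range(fp):
        out.append(MatchResult(0, 1, 0, [], 0.0))
    for _ in range(fn):
        out.append(MatchResult(0, 0, 1, [0.0], 0.0))
    return out


def test_summary_ratios_from_integer_counts():
    s = summarize_class(make_matches(93, 7, 0), ap=0.858)
    assert s.precision == pytest.approx(0.93)
    assert s.recall == pytest.approx(1.0)
    assert s.pct_tp == pytest.approx(93.0)
    assert s.pct_fp == pytest.approx(7.0)
    assert s.pct_fn == pytest.approx(0.0)
    assert s.f1 == pytest.approx(2 * 0.93 / 1.93)


def test_f1_is_harmonic_mean():
    assert f1_score(0.928, 1.000) == pytest.approx(0.963, abs=5e-4)
    assert f1_score(0.992, 0.999) == pytest.approx(0.995, abs=5e-4)
    assert f1_score(0.0, 0.0) is None


def test_recall_one_when_no_misses():
    s = summarize_class(make_matches(5, 0, 0), ap=1.0)
    assert s.recall == 1.0


def test_precision_undefined_without_predictions():
    s = summarize_class(make_matches(0, 0, 3), ap=0.0)
    assert s.precision is None
    assert s.recall == 0.0


def test_average_row_is_columnwise_mean():
    def row(miou, ap):
        return ClassSummary(None, None, None, miou, None, None, None, ap)

    per_class = {
        "shrapnel": row(0.681, 0.858), "vein": row(0.753, 0.955),
        "artery": row(0.784, 0.991), "nerve": row(0.709, 0.957),
    }
    avg = summarize_all(per_class)
    assert round(avg.miou, 3) == 0.732
    assert round(avg.ap, 3) == 0.940
    single = summarize_all({"only": per_class["vein"]})
    assert single.miou == per_class["vein"].miou


def test_miou_order_invariant_and_bounded():
    truths = [[BBox(0, 0, 10, 10)], [BBox(5, 5, 10, 10)], [BBox(0, 0, 8, 8)]]
    preds = [[det(1, 1, 10, 10)], [], [det(0, 0, 8, 8, 0.5)]]
    matches = [match_image(p, t) for p, t in zip(preds, truths)]
    s = summarize_class(matches, ap=None)
    rev = summarize_class(list(reversed(matches)), ap=None)
    assert s.miou == pytest.approx(rev.miou)
    assert s.miou <= max(m.image_iou for m in matches)


def test_evaluate_dataset_shapes_and_average_column():
    truths = [[BBox(0, 0, 10, 10, "artery"), BBox(30, 30, 8, 8, "vein")]]
    preds = [[det(0, 0, 10, 10, 0.9, "artery"), det(30, 30, 8, 8, 0.8, "vein")]]
    table, summaries, curves = evaluate_dataset(preds, truths)
    assert list(table.columns) == ["shrapnel", "vein", "artery", "nerve",
                                   "average"]
    assert table.loc["ap", "artery"] == pytest.approx(1.0)
    assert set(curves) == {"vein", "artery"}
    assert summaries["shrapnel"].ap is None
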