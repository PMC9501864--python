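"""Tests for the detector: schedule, architecture, codec, inference, training."""

from __future__ import annotations

import numpy as np
import pytest

from shrapod import BBox, Detection
from shrapod.model import (AnchorSet, ArchSpec, build_model, estimate_anchors,
                           load_model, lr_schedule, nms, predict, save_model,
                           train)
from shrapod.model.codec import box_from_targets, targets_from_box
from shrapod.model.training import TrainConfig, compute_loss
from shrapod.model.inference import normalize_image
from tests.conftest import tiny_arch, tiny_phantom_config


# --- learning-rate schedule --------------------------------------------------


class TestLrSchedule:
    def test_reaches_base_rate_at_end_of_warmup(self):
        assert lr_schedule(1000, 0.001, 1000) == pytest.approx(0.001)

    def test_quartic_values_during_warmup(self):
        assert lr_schedule(500, 0.001, 1000) == pytest.approx(6.25e-5)
        assert lr_schedule(1, 0.001, 1000) == pytest.approx(1e-15)

    def test_monotone_and_continuous_at_warmup(self):
        rates = [lr_schedule(i, 0.001, 1000) for i in range(1, 1005)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[999] == pytest.approx(0.001)      # iteration 1000
        assert rates[1000] == pytest.approx(0.001)     # constant after

    def test_optional_post_warmup_decay(self):
        assert lr_schedule(2000, 0.001, 1000, post_warmup_decay=True) == \
            pytest.approx(0.001 * (1000 / 2000) ** 4)

    def test_iteration_is_one_based(self):
        with pytest.raises(ValueError):
            lr_schedule(0)


# --- architecture ------------------------------------------------------------


def small_anchors():
    return AnchorSet(((40.0, 40.0), (30.0, 20.0), (16.0, 16.0), (10.0, 14.0)),
                     n_coarse=2)


class TestArchitecture:
    def test_grid_sizes_from_strides(self):
        assert ArchSpec(input_size=512).grid_sizes == (16, 32)
        assert ArchSpec(input_size=256).grid_sizes == (8, 16)

    def test_input_size_must_divide_strides(self):
        with pytest.raises(ValueError):
            ArchSpec(input_size=100)

    def test_head_output_shapes(self):
        model = build_model(tiny_arch(), small_anchors(), seed=0)
        outs = model.forward(np.zeros((2, 3, 96, 96), np.float32), train=False)
        assert outs[0].shape == (2, 2 * 9, 3, 3)    # coarse: 2 anchors
        assert outs[1].shape == (2, 2 * 9, 6, 6)    # fine: 2 anchors

    def test_class_count_only_changes_output_channels(self):
        m1 = build_model(tiny_arch(n_classes=1), small_anchors(), seed=0)
        m4 = build_model(tiny_arch(n_classes=4), small_anchors(), seed=0)
        p1, p4 = m1.params(), m4.params()
        assert len(p1) == len(p4)
        diff = [i for i, (a, b) in enumerate(zip(p1, p4))
                if a.value.shape != b.value.shape]
        # only the two 1x1 output convolutions differ
        assert len(diff) == 4

    def test_forward_on_zero_image_is_finite(self):
        model = build_model(tiny_arch(), small_anchors(), seed=0)
        outs = model.forward(np.zeros((1, 3, 96, 96), np.float32), train=False)
        assert all(np.isfinite(o).all() for o in outs)

    def test_wrong_spatial_size_rejected(self):
        model = build_model(tiny_arch(), small_anchors(), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 3, 64, 64), np.float32))


# --- box codec ---------------------------------------------------------------


def test_encode_decode_round_trip_recovers_boxes():
    rng = np.random.default_rng(0)
    for _ in range(50):
        anchor = tuple(rng.uniform(8, 80, 2))
        stride = int(rng.choice([16, 32]))
        box = BBox(*rng.uniform(0, 400, 2), *rng.uniform(4, 100, 2), "vein")
        cx, cy, ox, oy, tw, th = targets_from_box(box, anchor, stride)
        back = box_from_targets(cx, cy, ox, oy, tw, th, anchor, stride, "vein")
        for attr in ("x", "y", "w", "h"):
            assert getattr(back, attr) == pytest.approx(
                getattr(box, attr), abs=1e-6)
        assert 0.0 <= ox < 1.0 and 0.0 <= oy < 1.0


# --- inference ---------------------------------------------------------------


class TestInference:
    def test_nms_keeps_highest_confidence_of_duplicates(self):
        a = Detection(BBox(0, 0, 10, 10), 0.9)
        b = Detection(BBox(0, 0, 10, 10), 0.8)
        kept = nms([b, a], iou_thresh=0.5)
        assert kept == [a]

    def test_nms_keeps_disjoint_boxes(self):
        a = Detection(BBox(0, 0, 10, 10), 0.9)
        b = Detection(BBox(50, 50, 10, 10), 0.8)
        assert len(nms([a, b], 0.5)) == 2

    def test_confidence_threshold_one_gives_no_detections(self):
        model = build_model(tiny_arch(), small_anchors(), seed=0)
        img = np.random.default_rng(0).integers(0, 255, (96, 96, 3), np.uint8)
        assert predict(model, img, conf_threshold=1.0) == []

    def test_untrained_model_outputs_are_finite_and_clipped(self):
        model = build_model(tiny_arch(), small_anchors(), seed=0)
        img = np.random.default_rng(1).integers(0, 255, (96, 96, 3), np.uint8)
        dets = predict(model, img, conf_threshold=0.01)
        for d in dets:
            assert 0.0 <= d.confidence <= 1.0
            assert d.box.x >= 0 and d.box.y >= 0
            assert d.box.x2 <= 96 and d.box.y2 <= 96

    def test_normalize_image_range_and_layout(self):
        img = np.full((96, 96, 3), 255, np.uint8)
        x = normalize_image(img)
        assert x.shape == (3, 96, 96)
        assert x.max() == pytest.approx(0.5)


# --- training ----------------------------------------------------------------


def quick_setup(images, seed=0):
    boxes = [b for im in images for b in im.boxes]
    anchors = estimate_anchors(boxes, k=4, seed=seed)
    model = build_model(tiny_arch(), anchors, seed=seed)
    return model


class TestTraining:
    def test_loss_decreases_on_small_set(self, tiny_images):
        model = quick_setup(tiny_images)
        cfg = TrainConfig.desk(epochs=15, batch_size=8, warmup_iters=8,
                               base_lr=0.003, augment=False, seed=0)
        model, hist = train(model, list(tiny_images), None, cfg)
        assert hist.train_loss.iloc[-1] < 0.5 * hist.train_loss.iloc[0]

    def test_fixed_seed_reproduces_loss_curve(self, tiny_images):
        curves = []
        for _ in range(2):
            model = quick_setup(tiny_images, seed=3)
            cfg = TrainConfig.desk(epochs=3, batch_size=4, warmup_iters=8,
                                   seed=11)
            _, hist = train(model, list(tiny_images), None, cfg)
            curves.append(hist.train_loss.to_numpy())
        np.testing.assert_array_equal(curves[0], curves[1])

    def test_validation_loss_recorded_at_frequency(self, tiny_images):
        model = quick_setup(tiny_images)
        cfg = TrainConfig.desk(epochs=4, batch_size=4, warmup_iters=8,
                               val_frequency_iters=3, seed=0)
        _, hist = train(model, list(tiny_images[:6]), list(tiny_images[6:]),
                        cfg)
        recorded = hist.dropna(subset=["val_loss"])
        assert (recorded.iteration % 3 == 0).all()
        assert len(recorded) >= 1

    def test_missing_class_warns_but_trains(self, tiny_images):
        # strip all shrapnel boxes
        from shrapod.synth.phantom import AnnotatedImage

        stripped = [AnnotatedImage(im.pixels,
                                   [b for b in im.boxes if b.label != "shrapnel"],
                                   dict(im.meta))
                    for im in tiny_images[:4]]
        model = quick_setup(stripped)
        cfg = TrainConfig.desk(epochs=1, batch_size=4, warmup_iters=2, seed=0)
        with pytest.warns(UserWarning, match="shrapnel"):
            train(model, stripped, None, cfg)

    def test_empty_training_set_rejected(self):
        model = build_model(tiny_arch(), small_anchors(), seed=0)
        with pytest.raises(ValueError):
            train(model, [], None, TrainConfig.desk())

    def test_loss_gradient_matches_finite_difference(self, tiny_images):
        model = quick_setup(tiny_images)
        x = np.stack([normalize_image(im.pixels) for im in tiny_images[:2]])
        gts = [im.boxes for im in tiny_images[:2]]
        cfg = TrainConfig.desk()
        outs = model.forward(x, train=True)
        _, douts = compute_loss(outs, gts, model, cfg)
        model.backward(douts)
        p = model.params()[2]  # first fire squeeze weights
        idx = np.unravel_index(np.argmax(np.abs(p.grad)), p.grad.shape)
        eps, old = 1e-3, p.value[idx]

        def loss_at(v):
            p.value[idx] = v
            outs = model.forward(x, train=True)
            loss, _ = compute_loss(outs, gts, model, cfg)
            return loss["total"]

        num = (loss_at(old + eps) - loss_at(old - eps)) / (2 * eps)
        p.value[idx] = old
        assert p.grad[idx] == pytest.approx(num, rel=0.05)


def test_save_load_round_trip_preserves_predictions(tmp_path, tiny_images):
    model = quick_setup(tiny_images)
    img = tiny_images[0].pixels
    before = predict(model, img, conf_threshold=0.01)
    path = tmp_path / "ckpt.npz"
    save_model(model, path)
    after = predict(load_model(path), img, conf_threshold=0.01)
    assert len(before) == len(after)
    for a, b in zip(before, after):
        assert a.confidence == pytest.approx(b.confidence, abs=1e-6)
        assert a.box.x == pytest.approx(b.box.x, abs=1e-4)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(iou_penalty_threshold=1.5)
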