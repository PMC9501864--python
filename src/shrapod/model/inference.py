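"""Inference: forward pass, box decoding, thresholding and per-class NMS."""

from __future__ import annotations

import numpy as np

from ..boxes import CLASSES, BBox, Detection
from .codec import decode_head
from .network import HEAD_STRIDES, ShrapOD
from .nn import sigmoid

__all__ = ["predict", "predict_batch", "nms", "normalize_image"]


def normalize_image(pixels: np.ndarray) -> np.ndarray:
    """(S, S, 3) uint8/float raster → (3, S, S) float32 in [-0.5, 0.5]."""
    x = np.asarray(pixels, dtype=np.float32)
    if x.ndim == 2:
        x = np.repeat(x[:, :, None], 3, axis=2)
    if x.max() > 1.5:
        x = x / 255.0
    return np.ascontiguousarray(x.transpose(2, 0, 1)) - 0.5


def nms(dets: list[Detection], iou_thresh: float = 0.5) -> list[Detection]:
    """Greedy non-maximum suppression within one class."""
    from ..evaluation import iou as box_iou

    order = sorted(dets, key=lambda d: (-d.confidence, -d.box.area))
    kept: list[Detection] = []
    for d in order:
        if all(box_iou(d.box, k.box) < iou_thresh for k in kept):
            kept.append(d)
    return kept


def _decode_to_detections(outs, model: ShrapOD, image_size: int,
                          conf_threshold: float, nms_iou: float,
                          class_names) -> list[list[Detection]]:
    n_classes = model.arch.n_classes
    batch = outs[0].shape[0]
    per_image: list[list[Detection]] = [[] for _ in range(batch)]
    for out, anchors, stride in zip(outs, model.anchors.per_head(), HEAD_STRIDES):
        d = decode_head(out, anchors, stride, n_classes, sigmoid)
        score = d["obj"][..., None] * d["cls"]          # (N, A, G, G, C)
        hits = np.argwhere(score >= conf_threshold)
        for n, a, gy, gx, c in hits:
            box = BBox(float(d["x"][n, a, gy, gx]), float(d["y"][n, a, gy, gx]),
                       float(d["w"][n, a, gy, gx]), float(d["h"][n, a, gy, gx]),
                       class_names[c]).clip(image_size, image_size)
            if box.area <= 0:
                continue
            per_image[n].append(
                Detection(box, float(min(score[n, a, gy, gx, c], 1.0))))
    for n in range(batch):
        kept: list[Detection] = []
        for cls in class_names[:n_classes]:
            kept += nms([dd for dd in per_image[n] if dd.label == cls], nms_iou)
        per_image[n] = sorted(kept, key=lambda dd: -dd.confidence)
    return per_image


def predict_batch(model: ShrapOD, images: list[np.ndarray],
                  conf_threshold: float = 0.5, nms_iou: float = 0.5,
                  class_names=CLASSES, batch_size: int = 8) -> list[list[Detection]]:
    """Detections for a list of (S, S, 3) rasters."""
    results: list[list[Detection]] = []
    for i in range(0, len(images), batch_size):
        x = np.stack([normalize_image(im) for im in images[i:i + batch_size]])
        outs = model.forward(x, train=False)
        results += _decode_to_detections(outs, model, model.arch.input_size,
                                         conf_threshold, nms_iou, class_names)
    return results


def predict(model: ShrapOD, image: np.ndarray, conf_threshold: float = 0.5,
            nms_iou: float = 0.5, class_names=CLASSES) -> list[Detection]:
    """Detections for one image raster, boxes clipped to the frame."""
    return predict_batch(model, [image], conf_threshold, nms_iou,
                         class_names)[0]
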