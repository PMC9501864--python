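"""Detector training: SGDM, quartic-warmup schedule, YOLO-style loss.

Each ground-truth box is assigned to the anchor (across both heads)
whose centre-aligned shape best matches it, plus every anchor whose
shape IoU clears the assignment bar; those predictors receive
coordinate, objectness and class penalties.  All other predictors
receive a no-object penalty unless their decoded box overlaps some
ground truth above the IoU penalty threshold, in which case they are
excused (the "penalty threshold of < 0.5 IoU" rule).

Coordinate offsets use mean-squared error on the sigmoid-activated
centre offsets and the raw log-size terms; objectness and class scores
use binary cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..boxes import CLASSES
from ..synth.augment import augment_sample
from ..synth.phantom import AnnotatedImage
from .anchors import shape_iou
from .codec import decode_head, head_layout
from .inference import normalize_image
from .network import HEAD_STRIDES, ShrapOD
from .nn import SGDM, sigmoid
from .schedule import lr_schedule

__all__ = ["TrainConfig", "train", "compute_loss"]

_EPS = 1e-7


@dataclass
class TrainConfig:
    """Training hyperparameters (reference configuration by default)."""

    epochs: int = 125
    batch_size: int = 16
    base_lr: float = 0.001
    momentum: float = 0.9
    l2_reg: float = 0.0005
    warmup_iters: int = 1000
    iou_penalty_threshold: float = 0.5
    val_frequency_iters: int = 79
    n_anchors: int = 23
    seed: int = 0
    augment: bool = True
    post_warmup_decay: bool = False
    lambda_coord: float = 5.0
    lambda_obj: float = 1.0
    lambda_noobj: float = 0.5
    lambda_class: float = 1.0
    grad_clip: float = 10.0
    #: A ground truth is also assigned to every anchor whose centred
    #: shape IoU clears this bar (besides the single best anchor).
    anchor_assign_iou: float = 0.5
    #: Keep the parameters from the iteration with the lowest validation
    #: loss instead of the final iterate (needs a validation set).
    keep_best_val: bool = False

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "base_lr", "momentum", "l2_reg",
                     "warmup_iters", "val_frequency_iters", "n_anchors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.iou_penalty_threshold < 1.0:
            raise ValueError("iou_penalty_threshold must lie in (0, 1)")

    def lr_at(self, iteration: int) -> float:
        return lr_schedule(iteration, self.base_lr, self.warmup_iters,
                           self.post_warmup_decay)

    @classmethod
    def desk(cls, **kwargs) -> "TrainConfig":
        """Reduced CPU-scale profile: fewer epochs/anchors, shorter warmup."""
        defaults = dict(epochs=20, batch_size=8, n_anchors=6,
                        warmup_iters=100, base_lr=0.004,
                        val_frequency_iters=50, keep_best_val=True,
                        anchor_assign_iou=0.3)
        defaults.update(kwargs)
        return cls(**defaults)


def _bce(s: np.ndarray, t) -> np.ndarray:
    s = np.clip(s, _EPS, 1.0 - _EPS)
    return -(t * np.log(s) + (1.0 - t) * np.log(1.0 - s))


def _pairwise_iou_xywh(x, y, w, h, gt: np.ndarray) -> np.ndarray:
    """IoU of flattened predicted boxes against (M, 4) xywh ground truths."""
    px1, py1 = x.ravel(), y.ravel()
    px2, py2 = px1 + w.ravel(), py1 + h.ravel()
    gx1, gy1 = gt[:, 0], gt[:, 1]
    gx2, gy2 = gx1 + gt[:, 2], gy1 + gt[:, 3]
    ix = np.clip(np.minimum(px2[:, None], gx2) - np.maximum(px1[:, None], gx1), 0, None)
    iy = np.clip(np.minimum(py2[:, None], gy2) - np.maximum(py1[:, None], gy1), 0, None)
    inter = ix * iy
    union = (w.ravel() * h.ravel())[:, None] + (gt[:, 2] * gt[:, 3]) - inter
    return inter / np.maximum(union, 1e-12)


def compute_loss(outs: list[np.ndarray], gt_batch: list[list],
                 model: ShrapOD, config: TrainConfig,
                 class_names=CLASSES) -> tuple[dict, list[np.ndarray]]:
    """Loss components and gradients w.r.t. the raw head outputs.

    ``gt_batch`` holds, per image, a list of ground-truth ``BBox``.
    """
    n_classes = model.arch.n_classes
    cls_index = {name: i for i, name in enumerate(class_names[:n_classes])}
    batch = outs[0].shape[0]
    all_anchors = np.array(model.anchors.anchors, dtype=float)
    heads = model.anchors.per_head()
    head_of_anchor = [(0, i) for i in range(len(heads[0]))] + \
                     [(1, i) for i in range(len(heads[1]))]

    acts = [head_layout(o, len(a), n_classes).astype(np.float64)
            for o, a in zip(outs, heads)]
    sig = [dict(xy=sigmoid(a[:, :, 0:2]), obj=sigmoid(a[:, :, 4]),
                cls=sigmoid(a[:, :, 5:])) for a in acts]
    decoded = [decode_head(o, a, s, n_classes, sigmoid)
               for o, a, s in zip(outs, heads, HEAD_STRIDES)]

    # Target/weight tensors per head.
    tgt_xy = [np.zeros_like(s["xy"]) for s in sig]
    tgt_wh = [np.zeros_like(a[:, :, 2:4]) for a in acts]
    tgt_cls = [np.zeros_like(s["cls"]) for s in sig]
    assigned = [np.zeros(s["obj"].shape, dtype=bool) for s in sig]
    noobj_w = [np.full(s["obj"].shape, config.lambda_noobj) for s in sig]

    for n, gts in enumerate(gt_batch):
        if not gts:
            continue
        wh = np.array([[b.w, b.h] for b in gts], dtype=float)
        anchor_fit = shape_iou(wh, all_anchors)
        gt_xywh = np.array([[b.x, b.y, b.w, b.h] for b in gts], dtype=float)

        # Excuse confident predictors overlapping any ground truth.
        for h in range(2):
            d = decoded[h]
            iou_max = _pairwise_iou_xywh(
                d["x"][n], d["y"][n], d["w"][n], d["h"][n], gt_xywh
            ).max(axis=1).reshape(sig[h]["obj"].shape[1:])
            noobj_w[h][n][iou_max >= config.iou_penalty_threshold] = 0.0

        for g, box in enumerate(gts):
            chosen = set(np.flatnonzero(
                anchor_fit[g] >= config.anchor_assign_iou).tolist())
            chosen.add(int(anchor_fit[g].argmax()))
            for k in chosen:
                h, a = head_of_anchor[k]
                stride = HEAD_STRIDES[h]
                grid = acts[h].shape[-1]
                mx, my = box.x + box.w / 2.0, box.y + box.h / 2.0
                cx = min(int(mx // stride), grid - 1)
                cy = min(int(my // stride), grid - 1)
                anchor = heads[h][a]
                tgt_xy[h][n, a, 0, cy, cx] = mx / stride - cx
                tgt_xy[h][n, a, 1, cy, cx] = my / stride - cy
                tgt_wh[h][n, a, 0, cy, cx] = np.log(max(box.w, 1e-6) / anchor[0])
                tgt_wh[h][n, a, 1, cy, cx] = np.log(max(box.h, 1e-6) / anchor[1])
                assigned[h][n, a, cy, cx] = True
                if box.label in cls_index:
                    tgt_cls[h][n, a, :, cy, cx] = 0.0
                    tgt_cls[h][n, a, cls_index[box.label], cy, cx] = 1.0

    loss = dict(coord=0.0, obj=0.0, noobj=0.0, cls=0.0)
    douts = []
    for h in range(2):
        a, s = acts[h], sig[h]
        am = assigned[h][:, :, None]                     # broadcast over ch
        d = np.zeros_like(a)

        # coordinates (assigned predictors only)
        dxy = s["xy"] - tgt_xy[h]
        loss["coord"] += config.lambda_coord * float(
            ((dxy ** 2) * am).sum())
        d[:, :, 0:2] = (config.lambda_coord * 2.0 * dxy
                        * s["xy"] * (1.0 - s["xy"]) * am)
        dwh = a[:, :, 2:4] - tgt_wh[h]
        loss["coord"] += config.lambda_coord * float(((dwh ** 2) * am).sum())
        d[:, :, 2:4] = config.lambda_coord * 2.0 * dwh * am

        # objectness
        obj, asg = s["obj"], assigned[h]
        loss["obj"] += config.lambda_obj * float(_bce(obj, 1.0)[asg].sum())
        loss["noobj"] += float((noobj_w[h] * _bce(obj, 0.0))[~asg].sum())
        dobj = np.where(asg, config.lambda_obj * (obj - 1.0),
                        noobj_w[h] * obj)
        d[:, :, 4] = dobj

        # class scores (assigned predictors only)
        dcls = s["cls"] - tgt_cls[h]
        loss["cls"] += config.lambda_class * float(
            (_bce(s["cls"], tgt_cls[h]) * am).sum())
        d[:, :, 5:] = config.lambda_class * dcls * am

        d /= batch
        douts.append(d.reshape(outs[h].shape).astype(np.float32))

    for k in loss:
        loss[k] /= batch
    loss["total"] = sum(loss.values())
    return loss, douts


def _global_grad_clip(params, clip: float) -> None:
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if clip and total > clip:
        scale = clip / (total + 1e-12)
        for p in params:
            p.grad *= scale


def _eval_loss(model, images: list[AnnotatedImage], config,
               class_names) -> float:
    losses, counts = 0.0, 0
    for i in range(0, len(images), config.batch_size):
        chunk = images[i:i + config.batch_size]
        x = np.stack([normalize_image(im.pixels) for im in chunk])
        outs = model.forward(x, train=False)
        loss, _ = compute_loss(outs, [im.boxes for im in chunk], model,
                               config, class_names)
        losses += loss["total"] * len(chunk)
        counts += len(chunk)
    return losses / max(counts, 1)


def train(model: ShrapOD, train_set: list[AnnotatedImage],
          val_set: list[AnnotatedImage] | None, config: TrainConfig,
          class_names=CLASSES, verbose: bool = False
          ) -> tuple[ShrapOD, pd.DataFrame]:
    """Train in place; returns the model and a per-iteration history.

    Augmentation (when enabled) is applied to training samples only;
    validation images pass through untouched.
    """
    if not train_set:
        raise ValueError("empty training set")
    present = {b.label for im in train_set for b in im.boxes}
    missing = [c for c in class_names[:model.arch.n_classes]
               if c not in present]
    if missing:
        warnings.warn(f"training set has no boxes for classes: {missing}",
                      stacklevel=2)

    rng = np.random.default_rng(config.seed)
    opt = SGDM(model.params(), momentum=config.momentum, l2_reg=config.l2_reg)
    rows = []
    iteration = 0
    best_val, best_state = np.inf, None

    def snapshot():
        return ([p.value.copy() for p in model.params()],
                [(bn.running_mean.copy(), bn.running_var.copy())
                 for bn in model.batchnorms()])

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        for i in range(0, len(order), config.batch_size):
            iteration += 1
            chunk = [train_set[j] for j in order[i:i + config.batch_size]]
            if config.augment:
                chunk = [augment_sample(im, rng) for im in chunk]
            x = np.stack([normalize_image(im.pixels) for im in chunk])
            outs = model.forward(x, train=True)
            loss, douts = compute_loss(outs, [im.boxes for im in chunk],
                                       model, config, class_names)
            opt.zero_grad()
            model.backward(douts)
            _global_grad_clip(opt.params, config.grad_clip)
            lr = config.lr_at(iteration)
            opt.step(lr)

            row = dict(iteration=iteration, epoch=epoch, lr=lr,
                       train_loss=loss["total"], coord=loss["coord"],
                       obj=loss["obj"], noobj=loss["noobj"], cls=loss["cls"],
                       val_loss=np.nan)
            if val_set and iteration % config.val_frequency_iters == 0:
                row["val_loss"] = _eval_loss(model, val_set, config,
                                             class_names)
                if config.keep_best_val and row["val_loss"] < best_val:
                    best_val, best_state = row["val_loss"], snapshot()
            rows.append(row)
            if verbose and iteration % 10 == 0:
                print(f"iter {iteration:5d} epoch {epoch:3d} "
                      f"lr {lr:.2e} loss {loss['total']:.4f}")

    if val_set and config.keep_best_val:
        # one last validation so a strong final iterate is not discarded
        final_val = _eval_loss(model, val_set, config, class_names)
        if final_val < best_val:
            best_val, best_state = final_val, None
        if best_state is not None:
            values, bn_stats = best_state
            for p, v in zip(model.params(), values):
                p.value[...] = v
            for bn, (m_, v_) in zip(model.batchnorms(), bn_stats):
                bn.running_mean[...] = m_
                bn.running_var[...] = v_
    return model, pd.DataFrame(rows)
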