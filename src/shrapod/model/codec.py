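"""Encoding/decoding between boxes and YOLO head activations.

A head with stride ``s`` and anchor ``(aw, ah)`` predicts, per grid
cell ``(cx, cy)``:

* centre: ``bx = (cx + σ(tx)) · s``, ``by = (cy + σ(ty)) · s``
* size:   ``bw = aw · exp(tw)``,    ``bh = ah · exp(th)``
* objectness and per-class scores through sigmoids.

``targets_from_box`` inverts this mapping exactly (in float64), so an
encode/decode round trip recovers a box to machine precision.
"""

from __future__ import annotations

import numpy as np

from ..boxes import BBox

__all__ = ["targets_from_box", "box_from_targets", "decode_head",
           "head_layout"]

# Channel layout per anchor within a head output.
_TX, _TY, _TW, _TH, _OBJ = 0, 1, 2, 3, 4


def head_layout(out: np.ndarray, n_anchors: int,
                n_classes: int) -> np.ndarray:
    """Reshape (N, A*(5+C), G, G) → (N, A, 5+C, G, G)."""
    n, ch, gh, gw = out.shape
    if ch != n_anchors * (5 + n_classes):
        raise ValueError(f"head channel count {ch} != "
                         f"{n_anchors}*(5+{n_classes})")
    return out.reshape(n, n_anchors, 5 + n_classes, gh, gw)


def targets_from_box(box: BBox, anchor: tuple[float, float],
                     stride: int) -> tuple[int, int, float, float, float, float]:
    """Encode a box against an anchor at a head of the given stride.

    Returns ``(cell_x, cell_y, off_x, off_y, tw, th)`` where the
    offsets are the within-cell centre positions in [0, 1) that the
    sigmoid-activated tx/ty must reproduce.
    """
    mx = box.x + box.w / 2.0
    my = box.y + box.h / 2.0
    cell_x = int(mx // stride)
    cell_y = int(my // stride)
    off_x = mx / stride - cell_x
    off_y = my / stride - cell_y
    tw = float(np.log(box.w / anchor[0]))
    th = float(np.log(box.h / anchor[1]))
    return cell_x, cell_y, off_x, off_y, tw, th


def box_from_targets(cell_x: int, cell_y: int, off_x: float, off_y: float,
                     tw: float, th: float, anchor: tuple[float, float],
                     stride: int, label: str = "shrapnel") -> BBox:
    """Decode head activations back to an (x, y, w, h) box."""
    mx = (cell_x + off_x) * stride
    my = (cell_y + off_y) * stride
    w = anchor[0] * np.exp(tw)
    h = anchor[1] * np.exp(th)
    return BBox(mx - w / 2.0, my - h / 2.0, w, h, label)


def decode_head(out: np.ndarray, anchors, stride: int, n_classes: int,
                sigmoid_fn) -> dict[str, np.ndarray]:
    """Vectorised decode of one head output for a batch.

    Returns arrays ``x, y, w, h`` (box corners in pixels), ``obj``
    (sigmoid objectness) and ``cls`` (sigmoid class scores), all of
    shape (N, A, G, G) (cls with a trailing class axis).
    """
    a = head_layout(out, len(anchors), n_classes).astype(np.float64)
    n, na, _, gh, gw = a.shape
    cy, cx = np.mgrid[0:gh, 0:gw]
    sx = sigmoid_fn(a[:, :, _TX])
    sy = sigmoid_fn(a[:, :, _TY])
    aw = np.array([an[0] for an in anchors])[None, :, None, None]
    ah = np.array([an[1] for an in anchors])[None, :, None, None]
    bw = aw * np.exp(np.clip(a[:, :, _TW], -10, 10))
    bh = ah * np.exp(np.clip(a[:, :, _TH], -10, 10))
    bx = (cx[None, None] + sx) * stride
    by = (cy[None, None] + sy) * stride
    return {
        "x": bx - bw / 2.0, "y": by - bh / 2.0, "w": bw, "h": bh,
        "obj": sigmoid_fn(a[:, :, _OBJ]),
        "cls": np.moveaxis(sigmoid_fn(a[:, :, 5:]), 2, -1),
    }
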