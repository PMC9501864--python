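"""Dataset and report I/O: PNG rasters, COCO JSON, CSV mirrors, preprocessing.

The canonical annotation format is COCO JSON (category ids 1-4 =
shrapnel, vein, artery, nerve; ``bbox = [x, y, w, h]``, 0-based,
top-left origin, pixels).  Detections use the COCO results convention
(``image_id, category_id, bbox, score``).  CSV mirrors are provided
for spreadsheet-level inspection.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .boxes import CATEGORY_IDS, CATEGORY_NAMES, CLASSES, BBox, Detection
from .synth.phantom import AnnotatedImage

__all__ = [
    "save_png", "load_png", "write_coco", "read_coco",
    "write_detections", "read_detections", "boxes_to_csv", "csv_to_boxes",
    "preprocess", "sha256_file",
]


# --- rasters -----------------------------------------------------------------

def save_png(pixels: np.ndarray, path) -> None:
    Image.fromarray(pixels).save(path)


def load_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return arr[:, :, :3]


# --- COCO annotations --------------------------------------------------------

def write_coco(images: Sequence[AnnotatedImage], path,
               file_names: Sequence[str] | None = None) -> None:
    """Write ground-truth boxes for a dataset as COCO annotation JSON."""
    coco = {
        "images": [], "annotations": [],
        "categories": [{"id": i, "name": n} for n, i in CATEGORY_IDS.items()],
    }
    ann_id = 1
    for img_id, im in enumerate(images):
        name = file_names[img_id] if file_names else f"{img_id:06d}.png"
        coco["images"].append({
            "id": img_id, "file_name": name,
            "width": im.size, "height": im.size,
        })
        for b in im.boxes:
            coco["annotations"].append({
                "id": ann_id, "image_id": img_id,
                "category_id": CATEGORY_IDS[b.label],
                "bbox": [b.x, b.y, b.w, b.h],
                "area": b.area, "iscrowd": 0,
            })
            ann_id += 1
    Path(path).write_text(json.dumps(coco, indent=1))


def read_coco(path) -> tuple[list[list[BBox]], list[dict]]:
    """Read COCO annotations → (boxes per image, image records)."""
    coco = json.loads(Path(path).read_text())
    images = sorted(coco["images"], key=lambda r: r["id"])
    index = {rec["id"]: i for i, rec in enumerate(images)}
    names = {c["id"]: c["name"] for c in coco.get("categories", [])} or CATEGORY_NAMES
    boxes: list[list[BBox]] = [[] for _ in images]
    for ann in coco["annotations"]:
        x, y, w, h = ann["bbox"]
        boxes[index[ann["image_id"]]].append(
            BBox(x, y, w, h, names[ann["category_id"]]))
    return boxes, images


# --- COCO detection results --------------------------------------------------

def write_detections(dets_by_image: Sequence[Sequence[Detection]], path) -> None:
    records = []
    for img_id, dets in enumerate(dets_by_image):
        for d in dets:
            records.append({
                "image_id": img_id,
                "category_id": CATEGORY_IDS[d.label],
                "bbox": [d.box.x, d.box.y, d.box.w, d.box.h],
                "score": d.confidence,
            })
    Path(path).write_text(json.dumps(records, indent=1))


def read_detections(path, n_images: int | None = None) -> list[list[Detection]]:
    records = json.loads(Path(path).read_text())
    n = n_images or (max((r["image_id"] for r in records), default=-1) + 1)
    out: list[list[Detection]] = [[] for _ in range(n)]
    for r in records:
        x, y, w, h = r["bbox"]
        out[r["image_id"]].append(
            Detection(BBox(x, y, w, h, CATEGORY_NAMES[r["category_id"]]),
                      r["score"]))
    return out


# --- CSV mirrors -------------------------------------------------------------

def boxes_to_csv(boxes_by_image: Sequence[Sequence[BBox]], path) -> None:
    rows = [
        {"image_id": i, "class": b.label, "x": b.x, "y": b.y,
         "w": b.w, "h": b.h}
        for i, boxes in enumerate(boxes_by_image) for b in boxes
    ]
    pd.DataFrame(rows, columns=["image_id", "class", "x", "y", "w", "h"]
                 ).to_csv(path, index=False)


def csv_to_boxes(path) -> list[list[BBox]]:
    df = pd.read_csv(path)
    n = int(df["image_id"].max()) + 1 if len(df) else 0
    out: list[list[BBox]] = [[] for _ in range(n)]
    for r in df.to_dict("records"):
        out[int(r["image_id"])].append(
            BBox(r["x"], r["y"], r["w"], r["h"], r["class"]))
    return out


# --- preprocessing -----------------------------------------------------------

def preprocess(raster: np.ndarray, boxes: Sequence[BBox],
               crop: tuple[int, int, int, int] | None = None,
               size: int = 512) -> tuple[np.ndarray, list[BBox]]:
    """Crop (to remove on-screen instrument UI) then resize to size².

    ``crop`` is (x, y, w, h) in input pixels; box coordinates are
    mapped through the same affine transform.  Single-channel input is
    replicated to three identical channels.
    """
    from skimage.transform import resize as sk_resize

    arr = np.asarray(raster)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    H, W = arr.shape[:2]
    if crop is None:
        crop = (0, 0, W, H)
    cx, cy, cw, ch = crop
    if cx < 0 or cy < 0 or cx + cw > W or cy + ch > H or cw <= 0 or ch <= 0:
        raise ValueError(f"crop window {crop} outside raster {W}x{H}")
    cropped = arr[cy:cy + ch, cx:cx + cw]

    sx, sy = size / cw, size / ch
    if (cw, ch) == (size, size):
        out = cropped.copy()
    else:
        out = sk_resize(cropped.astype(np.float64), (size, size),
                        order=1, anti_aliasing=True, preserve_range=True)
        out = np.clip(np.rint(out), 0, 255).astype(arr.dtype)

    mapped = [BBox((b.x - cx) * sx, (b.y - cy) * sy, b.w * sx, b.h * sy,
                   b.label).clip(size, size) for b in boxes]
    return out, mapped


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
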