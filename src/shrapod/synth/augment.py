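"""Training-time augmentation: flips, ±20% scaling, ±360° rotation.

The raster and its boxes undergo the same similarity transform about
the image centre.  Axis-aligned boxes are transformed by mapping their
four corners and taking the enclosing axis-aligned rectangle, then
clipping to the frame — the standard detection-augmentation convention.
If any box would leave the frame entirely, the whole parameter draw is
resampled so the per-class box counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import transform as sktf

from ..boxes import BBox
from .phantom import AnnotatedImage

__all__ = ["AugmentParams", "sample_params", "augment_sample",
           "transform_box", "transform_image_plane", "IDENTITY_PARAMS"]


@dataclass(frozen=True)
class AugmentParams:
    flip_x: bool = False
    flip_y: bool = False
    scale: float = 1.0
    angle_deg: float = 0.0

    def matrix(self, size: int) -> np.ndarray:
        """3×3 forward transform in continuous (x, y) coordinates.

        Continuous coordinates treat pixel ``i`` as spanning
        ``[i, i + 1)``; the transform pivots about the frame centre
        ``size / 2``.  Boxes are mapped with this matrix.
        """
        c = size / 2.0
        t_in = np.array([[1, 0, -c], [0, 1, -c], [0, 0, 1]], dtype=float)
        f = np.diag([-1.0 if self.flip_x else 1.0,
                     -1.0 if self.flip_y else 1.0, 1.0])
        s = np.diag([self.scale, self.scale, 1.0])
        a = np.deg2rad(self.angle_deg)
        r = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1]], dtype=float)
        t_out = np.array([[1, 0, c], [0, 1, c], [0, 0, 1]], dtype=float)
        return t_out @ r @ s @ f @ t_in

    def index_matrix(self, size: int) -> np.ndarray:
        """The same transform in pixel-index coordinates (centres at
        integers), i.e. conjugated by the half-pixel shift; rasters are
        warped with this matrix so that a pure flip maps pixel centres
        onto pixel centres exactly."""
        half = np.array([[1, 0, 0.5], [0, 1, 0.5], [0, 0, 1]], dtype=float)
        inv_half = np.array([[1, 0, -0.5], [0, 1, -0.5], [0, 0, 1]], dtype=float)
        return inv_half @ self.matrix(size) @ half


IDENTITY_PARAMS = AugmentParams()


def sample_params(rng: np.random.Generator) -> AugmentParams:
    """Independent flips, uniform scale in [0.8, 1.2], rotation in ±360°."""
    return AugmentParams(
        flip_x=bool(rng.random() < 0.5),
        flip_y=bool(rng.random() < 0.5),
        scale=float(rng.uniform(0.8, 1.2)),
        angle_deg=float(rng.uniform(-360.0, 360.0)),
    )


def transform_box(box: BBox, matrix: np.ndarray) -> BBox:
    """Enclosing axis-aligned rectangle of the box's mapped corners."""
    pts = np.array([[cx, cy, 1.0] for cx, cy in box.corners()]).T
    mapped = matrix @ pts
    xs, ys = mapped[0], mapped[1]
    return BBox(float(xs.min()), float(ys.min()),
                float(xs.max() - xs.min()), float(ys.max() - ys.min()),
                box.label)


def transform_image_plane(plane: np.ndarray, params: AugmentParams,
                          order: int = 1) -> np.ndarray:
    """Warp one 2-D channel plane with the forward transform of ``params``.

    ``order=0`` (nearest) keeps binary masks crisp; rasters use bilinear.
    """
    m = params.index_matrix(plane.shape[0])
    tf = sktf.AffineTransform(matrix=m)
    warped = sktf.warp(plane.astype(np.float64), tf.inverse, order=order,
                       preserve_range=True, mode="constant", cval=0.0)
    return warped


def _boxes_survive(boxes: list[BBox], matrix: np.ndarray, size: int) -> bool:
    for b in boxes:
        if transform_box(b, matrix).clip(size, size).area <= 0.0:
            return False
    return True


def augment_sample(
    image: AnnotatedImage,
    rng: np.random.Generator,
    params: AugmentParams | None = None,
    max_retries: int = 25,
) -> AnnotatedImage:
    """Randomly augment one annotated image (raster + boxes together).

    Parameter draws under which any box fully exits the frame are
    resampled (up to ``max_retries``; the identity transform is used if
    no draw keeps every box in view).  Zero-area boxes after clipping
    are removed.
    """
    size = image.size
    if params is None:
        params = sample_params(rng)
        for _ in range(max_retries):
            if _boxes_survive(image.boxes, params.matrix(size), size):
                break
            params = sample_params(rng)
        else:
            params = IDENTITY_PARAMS

    m = params.matrix(size)
    warped = transform_image_plane(image.pixels[:, :, 0], params)
    plane = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    pixels = np.repeat(plane[:, :, None], 3, axis=2)

    boxes = []
    for b in image.boxes:
        tb = transform_box(b, m).clip(size, size)
        if tb.area > 0.0:
            boxes.append(tb)

    meta = dict(image.meta)
    meta["augmented"] = params
    return AnnotatedImage(pixels=pixels, boxes=boxes, meta=meta)
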