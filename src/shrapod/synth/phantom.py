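"""Rendering of annotated synthetic ultrasound phantom images.

The image formation model is deliberately simple — no wave propagation:
a piecewise mean echogenicity map (fat layer over muscle, bright bone
rim with an acoustic shadow, anechoic vessels, hypoechoic stippled
nerve, hyperechoic shrapnel rod) is multiplied by Rayleigh-distributed
speckle, smeared by an anisotropic point-spread blur, and log
compressed to 8 bits.  Ground-truth boxes are the tightest axis-aligned
rectangles around each feature's rendered support mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..boxes import BBox
from .config import PhantomConfig

__all__ = ["AnnotatedImage", "generate_phantom", "render_phantom",
           "PlacementError"]


class PlacementError(RuntimeError):
    """Raised when shrapnel cannot be placed clear of the vessels/nerve."""


@dataclass
class AnnotatedImage:
    """One synthetic frame with its ground-truth boxes and metadata."""

    pixels: np.ndarray  # (S, S, 3) uint8, identical channel planes
    boxes: list[BBox]
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def boxes_of(self, label: str) -> list[BBox]:
        return [b for b in self.boxes if b.label == label]


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:size, 0:size]
    return x.astype(np.float64), y.astype(np.float64)


def _ellipse_mask(x, y, cx, cy, rx, ry) -> np.ndarray:
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def _rod_mask(x, y, cx, cy, length, width, angle_rad) -> np.ndarray:
    """Rotated-rectangle footprint of the shrapnel rod."""
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = (x - cx) * ca + (y - cy) * sa       # along the rod axis
    v = -(x - cx) * sa + (y - cy) * ca      # across
    return (np.abs(u) <= length / 2.0) & (np.abs(v) <= width / 2.0)


def mask_to_box(mask: np.ndarray, label: str) -> BBox:
    """Tightest axis-aligned box around the True pixels of ``mask``."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask has no bounding box")
    return BBox(float(xs.min()), float(ys.min()),
                float(xs.max() - xs.min() + 1),
                float(ys.max() - ys.min() + 1), label)


def render_phantom(
    config: PhantomConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[BBox], dict[str, np.ndarray], dict]:
    """Render one phantom frame.

    Returns the uint8 raster (S, S, 3), the ground-truth boxes, the
    per-feature boolean support masks, and generation metadata.
    """
    S = config.image_size
    x, y = _grid(S)
    e = config.echogenicity

    # --- layered background -------------------------------------------------
    y_boundary = config.layer_boundary_frac * S
    wave = 0.004 * S * np.sin(2 * np.pi * x / S * rng.uniform(1.0, 2.5)
                              + rng.uniform(0, 2 * np.pi))
    mean = np.where(y < y_boundary + wave, e["fat"], e["muscle"])

    # heterogeneous muscle: a few smooth bright/dark agarose-like blobs
    for _ in range(rng.integers(3, 7)):
        bx = rng.uniform(0, S)
        by = rng.uniform(y_boundary + 0.05 * S, 0.95 * S)
        brx = rng.uniform(0.03, 0.10) * S
        bry = rng.uniform(0.01, 0.04) * S
        amp = rng.uniform(-0.10, 0.14)
        blob = amp * np.exp(-(((x - bx) / brx) ** 2 + ((y - by) / bry) ** 2))
        mean += np.where(y > y_boundary, blob, 0.0)

    # --- bone: bright upper rim with acoustic shadow below -------------------
    r_bone = config.mm(config.bone_diam_mm) / 2.0
    bone_cx = S / 2.0 + rng.uniform(-0.06, 0.06) * S
    bone_cy = 0.88 * S + r_bone * 0.35
    rim_outer = _ellipse_mask(x, y, bone_cx, bone_cy, r_bone, r_bone)
    rim_inner = _ellipse_mask(x, y, bone_cx, bone_cy, r_bone - 0.01 * S,
                              r_bone - 0.01 * S)
    bone_rim = rim_outer & ~rim_inner & (y < bone_cy)
    shadow = rim_inner | (rim_outer & (y >= bone_cy))
    mean = np.where(bone_rim, e["bone"], mean)
    mean = np.where(shadow, mean * 0.15, mean)
    bone_top = bone_cy - r_bone

    # --- neurovascular bundle ------------------------------------------------
    r_art = config.mm(config.artery_diam_mm) / 2.0
    b_vein = config.mm(config.vein_minor_mm) / 2.0     # semi-minor, vertical
    a_vein = b_vein * rng.uniform(1.25, 1.65)          # semi-major, horizontal
    r_nerve = config.mm(config.nerve_diam_mm) / 2.0
    gap = 0.25 * r_art

    depth_lo = y_boundary + r_art + 0.02 * S
    depth_hi = max(depth_lo + 1.0, min(bone_top - r_art - 0.04 * S, 0.75 * S))
    art_cy = rng.uniform(depth_lo, depth_hi)
    span_left = 2 * gap + 2 * a_vein
    span_right = 2 * gap + 2 * r_nerve
    cx_lo = span_left + r_art + 0.02 * S
    cx_hi = S - span_right - r_art - 0.02 * S
    if cx_lo >= cx_hi:
        raise PlacementError(
            "vein/artery/nerve bundle does not fit in the frame at this "
            "pixel scale")
    art_cx = rng.uniform(cx_lo, cx_hi)

    vein_cx = art_cx - r_art - gap - a_vein
    vein_cy = art_cy + rng.uniform(-0.3, 0.3) * b_vein
    nerve_cx = art_cx + r_art + gap + r_nerve
    nerve_cy = art_cy + rng.uniform(-0.3, 0.3) * r_nerve

    rim_w = 0.07 * r_art + 1.0
    artery_outer = _ellipse_mask(x, y, art_cx, art_cy, r_art + rim_w, r_art + rim_w)
    artery_lumen = _ellipse_mask(x, y, art_cx, art_cy, r_art, r_art)
    vein_outer = _ellipse_mask(x, y, vein_cx, vein_cy, a_vein + rim_w * 0.7,
                               b_vein + rim_w * 0.7)
    vein_lumen = _ellipse_mask(x, y, vein_cx, vein_cy, a_vein, b_vein)
    nerve_mask = _ellipse_mask(x, y, nerve_cx, nerve_cy, r_nerve, r_nerve)

    mean = np.where(nerve_mask, e["nerve"], mean)
    # honeycomb-like stipple inside the nerve
    stipple = rng.random((S, S)) < 0.12
    stipple = ndimage.binary_dilation(stipple, iterations=1)
    mean = np.where(nerve_mask & stipple, e["nerve"] + 0.35, mean)

    mean = np.where(vein_outer, e["vein_rim"], mean)
    mean = np.where(vein_lumen, e["vessel_lumen"], mean)
    mean = np.where(artery_outer, e["artery_rim"], mean)
    mean = np.where(artery_lumen, e["vessel_lumen"], mean)

    masks: dict[str, np.ndarray] = {
        "artery": artery_lumen,
        "vein": vein_lumen,
        "nerve": nerve_mask,
    }

    # --- shrapnel rod ---------------------------------------------------------
    has_shrapnel = bool(rng.random() < config.shrapnel_prob)
    shrapnel_mask = None
    if has_shrapnel:
        forbidden = ndimage.binary_dilation(
            artery_outer | vein_outer | nerve_mask,
            iterations=max(2, int(0.03 * S)))
        length = config.mm(rng.uniform(*config.shrapnel_len_mm))
        width = config.mm(config.shrapnel_diam_mm)
        half = (length + width) / 2.0 + 2.0
        cy_lo = y_boundary + half + 2
        cy_hi = min(bone_top - 2, 0.82 * S) - half
        if half + 2 >= S - half - 2 or cy_lo >= cy_hi:
            raise PlacementError(
                "shrapnel rod too large for the muscle region at this "
                "pixel scale")
        for _ in range(config.max_placement_retries):
            cx = rng.uniform(half + 2, S - half - 2)
            cy = rng.uniform(cy_lo, cy_hi)
            angle = rng.uniform(0, np.pi)
            rod = _rod_mask(x, y, cx, cy, length, width, angle)
            if rod.any() and not (rod & forbidden).any():
                shrapnel_mask = rod
                break
        else:
            raise PlacementError(
                "could not place shrapnel clear of the neurovascular bundle "
                f"after {config.max_placement_retries} retries")
        mean = np.where(shrapnel_mask, e["shrapnel"], mean)
        if config.shrapnel_shadow:
            shadow_cols = ndimage.binary_dilation(shrapnel_mask, iterations=1)
            below = np.cumsum(shadow_cols, axis=0) > 0
            mean = np.where(below & ~shrapnel_mask, mean * 0.5, mean)
        masks["shrapnel"] = shrapnel_mask

    # --- speckle, blur, log compression --------------------------------------
    amplitude = mean
    if config.speckle_scale > 0:
        # Rayleigh speckle normalised to unit mean, scaled contrast.
        ray = rng.rayleigh(scale=1.0, size=(S, S)) / np.sqrt(np.pi / 2.0)
        noise = 1.0 + config.speckle_scale * (ray - 1.0)
        amplitude = amplitude * np.clip(noise, 0.0, None)
    amplitude = ndimage.gaussian_filter(amplitude, sigma=(0.7, 1.4))
    g = config.log_gain
    img = np.log1p(g * np.clip(amplitude, 0.0, None)) / np.log1p(g * 1.5)
    img8 = np.clip(img * 255.0, 0, 255).astype(np.uint8)
    pixels = np.repeat(img8[:, :, None], 3, axis=2)

    boxes = [mask_to_box(m, label) for label, m in masks.items()
             if label != "shrapnel"]
    if shrapnel_mask is not None:
        boxes.append(mask_to_box(shrapnel_mask, "shrapnel"))
    meta = {"shrapnel_present": has_shrapnel}
    return pixels, boxes, masks, meta


def generate_phantom(config: PhantomConfig, seed: int) -> AnnotatedImage:
    """Generate one annotated phantom image, deterministic in (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, seed]))
    pixels, boxes, _, meta = render_phantom(config, rng)
    meta.update(seed=seed, split=None)
    return AnnotatedImage(pixels=pixels, boxes=boxes, meta=meta)


def generate_dataset(config: PhantomConfig, n: int,
                     start_seed: int = 0) -> list[AnnotatedImage]:
    """Generate ``n`` phantoms with consecutive per-image seeds."""
    return [generate_phantom(config, start_seed + i) for i in range(n)]
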