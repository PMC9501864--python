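"""Axis-aligned bounding boxes and detections.

Boxes follow the annotation convention used throughout the package:
``(x, y, w, h)`` in pixels, 0-based, top-left origin, with half-open
extent ``[x, x + w) × [y, y + h)``.  A box carries one class label from
:data:`CLASSES` (shrapnel fragment, vein, artery, nerve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Object classes, in canonical order.  COCO category ids are 1-based
#: into this tuple (1 = shrapnel, ..., 4 = nerve).
CLASSES: tuple[str, ...] = ("shrapnel", "vein", "artery", "nerve")

#: Neurovascular features the triage metric measures distance to.
NEUROVASCULAR: tuple[str, ...] = ("vein", "artery", "nerve")

CATEGORY_IDS: dict[str, int] = {name: i + 1 for i, name in enumerate(CLASSES)}
CATEGORY_NAMES: dict[int, str] = {i + 1: name for i, name in enumerate(CLASSES)}


@dataclass(frozen=True)
class BBox:
    """Axis-aligned rectangle ``(x, y, w, h)`` in pixels with a class label."""

    x: float
    y: float
    w: float
    h: float
    label: str = "shrapnel"

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.w, self.h))):
            raise ValueError("box coordinates must be finite")
        if self.w < 0 or self.h < 0:
            raise ValueError("box width and height must be non-negative")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    def corners(self) -> list[tuple[float, float]]:
        """Four corners, clockwise from top-left."""
        return [
            (self.x, self.y),
            (self.x2, self.y),
            (self.x2, self.y2),
            (self.x, self.y2),
        ]

    def clip(self, width: float, height: float) -> "BBox":
        """Intersect the box with the frame ``[0, width) × [0, height)``."""
        x1 = min(max(self.x, 0.0), width)
        y1 = min(max(self.y, 0.0), height)
        x2 = min(max(self.x2, 0.0), width)
        y2 = min(max(self.y2, 0.0), height)
        return BBox(x1, y1, max(x2 - x1, 0.0), max(y2 - y1, 0.0), self.label)

    def translate(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x + dx, self.y + dy, self.w, self.h, self.label)

    def scale(self, s: float) -> "BBox":
        """Scale all coordinates about the origin."""
        return BBox(self.x * s, self.y * s, self.w * s, self.h * s, self.label)


@dataclass(frozen=True)
class Detection:
    """A predicted box with a confidence score in ``[0, 1]``."""

    box: BBox
    confidence: float = 1.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence!r} outside [0, 1]")

    @property
    def label(self) -> str:
        return self.box.label
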