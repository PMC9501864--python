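"""Deterministic train/validation/test partitioning (75/10/15 default)."""

from __future__ import annotations

import numpy as np

from .phantom import AnnotatedImage

__all__ = ["split_dataset", "DEFAULT_FRACTIONS"]

DEFAULT_FRACTIONS: tuple[float, float, float] = (0.75, 0.10, 0.15)
_SPLIT_NAMES = ("train", "val", "test")


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    leftover = n - sum(sizes)
    for i in sorted(range(len(fractions)), key=lambda i: -remainders[i])[:leftover]:
        sizes[i] += 1
    # No split with a nonzero fraction may end up empty: borrow from the
    # currently largest split.
    for i, f in enumerate(fractions):
        while f > 0 and sizes[i] == 0:
            j = int(np.argmax(sizes))
            sizes[j] -= 1
            sizes[i] += 1
    return sizes


def split_dataset(
    images: list[AnnotatedImage],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> tuple[list[AnnotatedImage], list[AnnotatedImage], list[AnnotatedImage]]:
    """Shuffle and partition images into train/val/test lists.

    Sizes follow largest-remainder rounding of the fractions; the
    partition is deterministic for a fixed seed, the union of the
    outputs equals the input, and each image's ``meta['split']`` tag is
    set.  Validation/test images are never augmented downstream.
    """
    if len(fractions) != 3:
        raise ValueError("expected three fractions (train, val, test)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(images)
    if n < 3:
        raise ValueError(f"need at least 3 images to split, got {n}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = _largest_remainder(n, tuple(fractions))

    out: list[list[AnnotatedImage]] = []
    start = 0
    for name, k in zip(_SPLIT_NAMES, sizes):
        part = [images[i] for i in order[start:start + k]]
        for im in part:
            im.meta["split"] = name
        out.append(part)
        start += k
    return out[0], out[1], out[2]
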