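"""Integral images (summed-area tables) and Haar rectangle features.

These are the primitives underneath cascade-style face detection: the
integral image turns the sum of any axis-aligned rectangle of pixels into
four table lookups, and a Haar feature is the difference between the pixel
sums of adjacent "dark" and "light" rectangles.  The trained cascade itself
is a pluggable backend (see :mod:`chewcount.landmarks`); this module provides
the exact arithmetic layer, which is also handy for building toy detectors
in tests.

Coordinate convention: arrays are indexed ``[row, col]`` (NumPy order); the
``Rect`` type uses image convention ``x = column``, ``y = row`` with 0-based
top-left origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidRectError

__all__ = [
    "Rect",
    "HaarFeature",
    "compute_integral_image",
    "box_sum",
    "haar_value",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: top-left corner (x, y), extents (w, h) in pixels."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise InvalidRectError(f"rectangle extents must be >= 1, got w={self.w} h={self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h


@dataclass(frozen=True)
class HaarFeature:
    """Dark-minus-light rectangle feature.

    ``kind`` is one of ``two-rectangle``, ``three-rectangle``,
    ``four-rectangle`` — the classic edge / line / diagonal configurations.
    The value is ``sum(dark rects) - sum(light rects)`` of source intensities.
    """

    kind: str
    dark_rects: tuple[Rect, ...]
    light_rects: tuple[Rect, ...]

    _KINDS = ("two-rectangle", "three-rectangle", "four-rectangle")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidInputError(f"unknown Haar feature kind {self.kind!r}")
        if not self.dark_rects or not self.light_rects:
            raise InvalidInputError("Haar feature needs at least one dark and one light rect")
        n = len(self.dark_rects) + len(self.light_rects)
        expected = {"two-rectangle": 2, "three-rectangle": 3, "four-rectangle": 4}[self.kind]
        if n != expected:
            raise InvalidInputError(f"{self.kind} feature must have {expected} rects, got {n}")


def compute_integral_image(img: np.ndarray) -> np.ndarray:
    """Summed-area table of a grayscale image, in a single pass.

    Entry ``[r, c]`` is the sum of all source pixels with row <= r and
    col <= c (inclusive).  Integer inputs stay exact (int64 accumulator).
    """
    a = np.asarray(img)
    if a.ndim != 2 or a.size == 0:
        raise InvalidInputError(f"expected a non-empty 2-D image, got shape {a.shape}")
    dtype = np.int64 if np.issubdtype(a.dtype, np.integer) or a.dtype == np.bool_ else np.float64
    return a.astype(dtype).cumsum(axis=0).cumsum(axis=1)


def box_sum(ii: np.ndarray, r: Rect) -> float:
    """Sum of source intensities inside ``r`` using four table lookups.

    Rectangles touching row/column 0 use the standard convention of a
    conceptual zero row/column outside the table.
    """
    h, w = ii.shape
    if r.x < 0 or r.y < 0 or r.x + r.w > w or r.y + r.h > h:
        raise InvalidRectError(f"{r} outside {w}x{h} image bounds")
    r2, c2 = r.y + r.h - 1, r.x + r.w - 1
    total = ii[r2, c2]
    if r.y > 0:
        total = total - ii[r.y - 1, c2]
    if r.x > 0:
        total = total - ii[r2, r.x - 1]
    if r.y > 0 and r.x > 0:
        total = total + ii[r.y - 1, r.x - 1]
    return total


def haar_value(ii: np.ndarray, f: HaarFeature) -> float:
    """Feature response: dark-region pixel sum minus light-region pixel sum."""
    dark = sum(box_sum(ii, r) for r in f.dark_rects)
    light = sum(box_sum(ii, r) for r in f.light_rects)
    return dark - light


def scan_feature(ii: np.ndarray, f: HaarFeature, stride: int = 1) -> np.ndarray:
    """Evaluate a Haar feature at every in-bounds offset of the image.

    Returns an array of responses indexed by (row, col) offset.  Used by the
    toy template detector; a trained cascade would combine many such maps.
    """
    rects = f.dark_rects + f.light_rects
    fw = max(r.x + r.w for r in rects)
    fh = max(r.y + r.h for r in rects)
    h, w = ii.shape
    rows = range(0, h - fh + 1, stride)
    cols = range(0, w - fw + 1, stride)
    out = np.empty((len(rows), len(cols)))
    for i, dy in enumerate(rows):
        for j, dx in enumerate(cols):
            shifted = HaarFeature(
                f.kind,
                tuple(Rect(r.x + dx, r.y + dy, r.w, r.h) for r in f.dark_rects),
                tuple(Rect(r.x + dx, r.y + dy, r.w, r.h) for r in f.light_rects),
            )
            out[i, j] = haar_value(ii, shifted)
    return out


def two_rect_feature(x: int, y: int, w: int, h: int, orientation: str = "horizontal") -> HaarFeature:
    """Convenience constructor for the classic two-rectangle edge feature."""
    if orientation == "horizontal":
        if h % 2:
            raise InvalidInputError("horizontal two-rect feature needs even height")
        half = h // 2
        return HaarFeature("two-rectangle", (Rect(x, y, w, half),), (Rect(x, y + half, w, half),))
    if orientation == "vertical":
        if w % 2:
            raise InvalidInputError("vertical two-rect feature needs even width")
        half = w // 2
        return HaarFeature("two-rectangle", (Rect(x, y, half, h),), (Rect(x + half, y, half, h),))
    raise InvalidInputError(f"unknown orientation {orientation!r}")


def rect_iou(a: Rect, b: Rect) -> float:
    """Intersection-over-union of two rectangles (0 when disjoint)."""
    ix = max(0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def rects_cover(feature_rects: Sequence[Rect], width: int, height: int) -> bool:
    """True when every rect of a feature lies inside a width x height image."""
    return all(0 <= r.x and 0 <= r.y and r.x + r.w <= width and r.y + r.h <= height for r in feature_rects)
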