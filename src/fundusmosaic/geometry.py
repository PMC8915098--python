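"""Shared geometric and raster types.

Coordinate conventions used throughout the package:

* pixel coordinates are 0-based with the origin at the top-left corner,
  ``x`` increasing rightward (columns) and ``y`` increasing downward (rows);
* bounding boxes are half-open: the pixel column ``x_max`` and row ``y_max``
  are *excluded*, so ``area = (x_max - x_min) * (y_max - y_min)`` counts
  covered pixels exactly;
* circle centers may be sub-pixel (floats); boxes are integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "BBox",
    "Circle",
    "Homography",
    "bbox_area",
    "bbox_intersection",
    "bbox_union_area",
]


@dataclass
class Frame:
    """One RGB raster with identity, the unit flowing through detection.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        8-bit RGB image data.
    source_id : str
        Identifier of the originating video or image file.
    index : int
        Temporal/lexicographic position within the source.
    """

    pixels: np.ndarray
    source_id: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"Frame requires an (H, W, 3) RGB raster, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("Frame must have height >= 1 and width >= 1")
        if self.index < 0:
            raise ValueError("Frame index must be non-negative")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class BBox:
    """Axis-aligned integer box, half-open on both axes."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_min < self.x_max):
            raise ValueError(f"invalid x extent: [{self.x_min}, {self.x_max})")
        if not (0 <= self.y_min < self.y_max):
            raise ValueError(f"invalid y extent: [{self.y_min}, {self.y_max})")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class Circle:
    """Circle with sub-pixel center and positive radius, in pixel units."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"circle radius must be positive, got {self.r}")


@dataclass
class Homography:
    """3x3 planar projective map, normalized so h[2, 2] == 1.

    Maps following-image coordinates (x, y) into base-image coordinates.
    """

    h: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {h.shape}")
        if abs(np.linalg.det(h)) < 1e-12:
            raise ValueError("homography must be invertible")
        if abs(h[2, 2]) < 1e-12:
            raise ValueError("homography h33 must be non-zero for normalization")
        self.h = h / h[2, 2]

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.h))

    def compose(self, other: "Homography") -> "Homography":
        """Return the map equal to applying ``other`` first, then ``self``."""
        return Homography(self.h @ other.h)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points."""
        pts = np.asarray(points, dtype=float)
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        homog = np.column_stack([pts, np.ones(len(pts))])
        out = homog @ self.h.T
        out = out[:, :2] / out[:, 2:3]
        return out[0] if squeeze else out


def bbox_area(b: BBox) -> int:
    """Area of a half-open box in pixels squared."""
    return b.width * b.height


def bbox_intersection(a: BBox, b: BBox) -> BBox | None:
    """Half-open intersection box of ``a`` and ``b``, or None when disjoint."""
    x_min = max(a.x_min, b.x_min)
    y_min = max(a.y_min, b.y_min)
    x_max = min(a.x_max, b.x_max)
    y_max = min(a.y_max, b.y_max)
    if x_min >= x_max or y_min >= y_max:
        return None
    return BBox(x_min, y_min, x_max, y_max)


def bbox_union_area(a: BBox, b: BBox) -> int:
    """Area of the union of two boxes (inclusion-exclusion)."""
    inter = bbox_intersection(a, b)
    inter_area = bbox_area(inter) if inter is not None else 0
    return bbox_area(a) + bbox_area(b) - inter_area
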