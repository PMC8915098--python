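"""Classical retinal-region detector.

Chain: red channel -> Gaussian blur -> Otsu binarization -> contour image ->
Circle Hough Transform -> enclosing square. One retina per frame is assumed;
only the top-voted circle candidate is promoted to a detection. The detector
is a plain ``Frame -> DetectionResult`` contract, so a learned detector can
be substituted.

Also hosts the closed-form single-stage detector-config arithmetic
(``derive_yolo_config``) used to parameterize an external YOLO-style network;
the network itself is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import hough_circle as _sk_hough_circle
from skimage.transform import hough_circle_peaks as _sk_hough_circle_peaks

from .geometry import BBox, Circle, Frame

__all__ = [
    "ChtParams",
    "DetectionResult",
    "YoloConfigParams",
    "extract_red_channel",
    "blur",
    "otsu_threshold",
    "contour_image",
    "hough_circles",
    "circle_to_bbox",
    "detect_retina",
    "derive_yolo_config",
]

# Hough accumulator arrays are len(radii) * H * W; cap the working resolution.
_MAX_HOUGH_SIDE = 512
_MAX_HOUGH_RADII = 48


@dataclass
class ChtParams:
    """Circle-Hough-Transform search parameters.

    Radius bounds are fractions of ``min(height, width)``; the minimum
    center-to-center distance between reported candidates is a fraction of
    the image diagonal. ``accumulator_threshold`` is on the perimeter-
    normalized accumulator (1.0 = a fully supported circle).
    """

    min_radius_frac: float = 0.10
    max_radius_frac: float = 0.45
    accumulator_threshold: float = 0.25
    min_center_distance_frac: float = 0.10
    blur_kernel: int = 9

    def __post_init__(self) -> None:
        if not (0 < self.min_radius_frac < self.max_radius_frac <= 0.5):
            raise ValueError(
                "require 0 < min_radius_frac < max_radius_frac <= 0.5, got "
                f"{self.min_radius_frac}, {self.max_radius_frac}"
            )
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError(f"blur_kernel must be odd and >= 1, got {self.blur_kernel}")
        if self.accumulator_threshold <= 0:
            raise ValueError("accumulator_threshold must be positive")


@dataclass
class DetectionResult:
    """Outcome of the detector on one frame.

    ``circle`` and ``bbox`` are both present (successful detection) or both
    ``None``; ``bbox`` is the image-clipped enclosing square of ``circle``.
    ``diagnostics`` carries the Otsu threshold used, the number of circle
    candidates, and the top accumulator score.
    """

    circle: Circle | None
    bbox: BBox | None
    method: str = "cht"
    diagnostics: dict = field(default_factory=dict)

    @property
    def detected(self) -> bool:
        return self.bbox is not None


@dataclass(frozen=True)
class YoloConfigParams:
    classes: int
    max_batches: int
    steps: tuple[int, int]
    filters: int


def extract_red_channel(img: Frame | np.ndarray) -> np.ndarray:
    """Return the R plane of an RGB image as 8-bit grayscale."""
    pixels = img.pixels if isinstance(img, Frame) else np.asarray(img)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {pixels.shape}")
    return np.ascontiguousarray(pixels[:, :, 0])


def blur(img: np.ndarray, kernel: int) -> np.ndarray:
    """Gaussian low-pass with a square ``kernel x kernel`` support.

    ``kernel`` must be odd; ``kernel == 1`` is the identity. The sigma is
    derived from the kernel size with the usual ``0.3*((k-1)/2 - 1) + 0.8``
    convention so the kernel radius matches ``(k-1)/2``.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"blur kernel must be odd and >= 1, got {kernel}")
    img = np.asarray(img)
    if kernel == 1:
        return img.copy()
    sigma = 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8
    radius = (kernel - 1) // 2
    out = ndi.gaussian_filter(img.astype(np.float64), sigma=sigma, truncate=radius / sigma)
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return out


def otsu_threshold(img: np.ndarray) -> tuple[np.ndarray, float]:
    """Binarize by the threshold maximizing between-class variance.

    Works on the 256-bin histogram of an 8-bit image. Candidate thresholds
    ``t`` split pixels into ``<= t`` and ``> t``; among equally optimal
    thresholds the plateau mean is returned (so a perfectly bimodal image
    yields a threshold midway between its two modes). Returns
    ``(mask, threshold)`` with ``mask = 1`` above the threshold.

    Raises ``ValueError`` on a constant image (no valid split exists).
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        img = np.clip(np.floor(np.asarray(img, dtype=np.float64) + 0.5), 0, 255).astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: Otsu threshold is undefined")

    # between-class variance for every candidate split t in 0..254
    w0 = np.cumsum(hist)[:-1]
    w1 = n - w0
    cum_mean = np.cumsum(hist * np.arange(256))[:-1]
    total_mean = (hist * np.arange(256)).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (total_mean - cum_mean) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between, nan=-1.0)
    best = var_between.max()
    plateau = np.flatnonzero(var_between == best)
    threshold = float(plateau.mean())
    mask = (img > threshold).astype(np.uint8)
    return mask, threshold


def contour_image(mask: np.ndarray) -> np.ndarray:
    """Boundary image: white (255) background, black (0) component outlines.

    A foreground pixel is a boundary pixel when any of its 8 neighbours is
    background (or lies outside the raster).
    """
    mask = np.asarray(mask).astype(bool)
    interior = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    boundary = mask & ~interior
    out = np.full(mask.shape, 255, dtype=np.uint8)
    out[boundary] = 0
    return out


def _radius_window(shape: tuple[int, int], p: ChtParams) -> np.ndarray:
    ref = min(shape[0], shape[1])
    r_min = max(1, math.ceil(p.min_radius_frac * ref))
    r_max = max(r_min, math.floor(p.max_radius_frac * ref))
    step = max(1, (r_max - r_min) // _MAX_HOUGH_RADII)
    return np.arange(r_min, r_max + 1, step)


def hough_circles(edges: np.ndarray, p: ChtParams) -> list[tuple[Circle, float]]:
    """Vote-ranked circle candidates from a contour image.

    ``edges`` is a white-background/black-lines raster (dark pixels are the
    edge evidence). Candidates below ``p.accumulator_threshold`` are dropped;
    an empty list is a valid outcome. Ties are broken deterministically:
    larger radius first, then smaller center y, then smaller center x.
    """
    edges = np.asarray(edges)
    edge_bool = edges < 128 if edges.dtype == np.uint8 else edges.astype(bool)
    if not edge_bool.any():
        return []
    radii = _radius_window(edge_bool.shape, p)
    hspaces = _sk_hough_circle(edge_bool, radii)
    diag = math.hypot(*edge_bool.shape)
    min_dist = max(1, int(p.min_center_distance_frac * diag))
    accums, cx, cy, rr = _sk_hough_circle_peaks(
        hspaces,
        radii,
        min_xdistance=min_dist,
        min_ydistance=min_dist,
        threshold=p.accumulator_threshold,
        total_num_peaks=10,
    )
    order = sorted(
        range(len(accums)),
        key=lambda i: (-accums[i], -rr[i], cy[i], cx[i]),
    )
    return [
        (Circle(float(cx[i]), float(cy[i]), float(rr[i])), float(accums[i])) for i in order
    ]


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def circle_to_bbox(c: Circle, img_w: int, img_h: int) -> BBox:
    """Enclosing square of a circle, clipped to the image bounds.

    Clipping may break squareness at borders. Raises ``ValueError`` when the
    circle lies entirely outside the image.
    """
    if img_w < 1 or img_h < 1:
        raise ValueError("image dimensions must be positive")
    x_min = max(0, _round_half_away(c.cx - c.r))
    y_min = max(0, _round_half_away(c.cy - c.r))
    x_max = min(img_w, _round_half_away(c.cx + c.r))
    y_max = min(img_h, _round_half_away(c.cy + c.r))
    if x_min >= x_max or y_min >= y_max:
        raise ValueError(f"circle {c} lies outside the {img_w}x{img_h} image")
    return BBox(x_min, y_min, x_max, y_max)


def _block_reduce_max(mask: np.ndarray, f: int) -> np.ndarray:
    h, w = mask.shape
    hp, wp = math.ceil(h / f) * f, math.ceil(w / f) * f
    padded = np.zeros((hp, wp), dtype=bool)
    padded[:h, :w] = mask
    return padded.reshape(hp // f, f, wp // f, f).any(axis=(1, 3))


def detect_retina(img: Frame, p: ChtParams | None = None) -> DetectionResult:
    """Run the full classical chain on one frame.

    Red channel -> blur -> Otsu -> contour image -> CHT; the top-voted circle
    becomes the detection, as an image-clipped enclosing square. A frame
    where the chain degenerates (constant image, no circle candidate) yields
    a result with ``circle``/``bbox`` absent and diagnostics populated.

    For speed the Hough voting runs on an edge map downscaled so that the
    longer side is at most 512 px; the recovered circle is scaled back.
    """
    if p is None:
        p = ChtParams()
    red = extract_red_channel(img)
    blurred = blur(red, p.blur_kernel)
    diagnostics: dict = {"threshold": None, "n_candidates": 0, "score": None}
    try:
        mask, threshold = otsu_threshold(blurred)
    except ValueError:
        return DetectionResult(None, None, diagnostics=diagnostics)
    diagnostics["threshold"] = threshold
    edges = contour_image(mask)

    h, w = edges.shape
    f = max(1, math.ceil(max(h, w) / _MAX_HOUGH_SIDE))
    edge_bool = edges < 128
    if f > 1:
        edge_bool = _block_reduce_max(edge_bool, f)
    candidates = hough_circles(np.where(edge_bool, 0, 255).astype(np.uint8), p)
    diagnostics["n_candidates"] = len(candidates)
    if not candidates:
        return DetectionResult(None, None, diagnostics=diagnostics)
    (c, score) = candidates[0]
    diagnostics["score"] = score
    if f > 1:
        # map coarse-grid circle back to full resolution (cell centers)
        c = Circle(c.cx * f + (f - 1) / 2, c.cy * f + (f - 1) / 2, c.r * f)
    try:
        bbox = circle_to_bbox(c, w, h)
    except ValueError:
        return DetectionResult(None, None, diagnostics=diagnostics)
    return DetectionResult(c, bbox, diagnostics=diagnostics)


def derive_yolo_config(classes: int) -> YoloConfigParams:
    """Closed-form per-class config arithmetic for a YOLO-style detector.

    ``max_batches = max(2000 * classes, 6000)``; ``steps`` are 80% and 90%
    of ``max_batches``; ``filters = (classes + 5) * 3``.
    """
    if classes < 1:
        raise ValueError(f"classes must be >= 1, got {classes}")
    max_batches = max(2000 * classes, 6000)
    steps = (int(0.8 * max_batches), int(0.9 * max_batches))
    filters = (classes + 5) * 3
    return YoloConfigParams(classes, max_batches, steps, filters)
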