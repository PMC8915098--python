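"""Synthetic fundus-like frames and sequences with known ground truth.

Emulates low-quality smartphone-ophthalmoscope footage: a near-black noisy
surround, a small bright circular retinal window with radial intensity
falloff and red-dominant tissue color, a bright optic-disc blob, dark vessel
curves, small frame-to-frame motion, and per-frame illumination jitter.
Every raster and every ground-truth quantity is a deterministic function of
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.transform import ProjectiveTransform, warp

from .detect import circle_to_bbox
from .geometry import BBox, Circle, Frame, Homography

__all__ = ["SyntheticScene", "SyntheticSequence", "make_fundus_frame", "make_sequence"]


@dataclass
class SyntheticScene:
    """A master fundus-like image with its known retina geometry."""

    image: np.ndarray  # (H, W, 3) uint8
    circle: Circle
    seed: int


@dataclass
class SyntheticSequence:
    """Frames derived from one scene by known homographies.

    ``gt_homographies[i]`` maps frame ``i`` coordinates to frame 0
    coordinates (frame 0 is the unwarped scene; entry 0 is the identity).
    """

    frames: list[Frame]
    gt_boxes: list[BBox]
    gt_homographies: list[Homography]
    illumination: list[float]


def _radial_falloff(width: int, height: int, circle: Circle) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    d = np.hypot(xx - circle.cx, yy - circle.cy) / circle.r
    return np.clip(1.0 - 0.55 * d**2, 0.0, 1.0)


def _stamp_polyline(
    canvas: np.ndarray, points: np.ndarray, half_width: float, color: np.ndarray
) -> None:
    h, w = canvas.shape[:2]
    for x, y in points:
        rr, cc = _draw_disk((y, x), max(1.0, half_width), shape=(h, w))
        canvas[rr, cc] = color


def make_fundus_frame(
    width: int,
    height: int,
    circle: Circle,
    n_vessels: int = 6,
    seed: int = 0,
    background_sigma: float = 4.0,
    contrast: float = 2.0,
) -> SyntheticScene:
    """Render a deterministic fundus-like scene with known retina circle.

    The retinal window is a bright red-dominant disc with radial falloff, an
    off-center optic-disc blob, and ``n_vessels`` dark curves random-walking
    from the optic disc outward. The surround is near-black sensor noise.
    The construction guarantees the red-channel mean inside the circle
    exceeds the outside mean by at least ``contrast``.
    """
    if circle.r >= min(width, height) / 2:
        raise ValueError(
            f"retina radius {circle.r} too large for a {width}x{height} frame"
        )
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width, 3), dtype=np.float64)
    img += rng.normal(6.0, background_sigma, size=img.shape)

    # retinal window: red-dominant tissue with radial falloff and a fixed
    # choroidal speckle pattern (gives registration realistic fine texture)
    yy, xx = np.mgrid[0:height, 0:width]
    inside = (np.hypot(xx - circle.cx, yy - circle.cy) <= circle.r)
    falloff = _radial_falloff(width, height, circle)
    from scipy.ndimage import gaussian_filter

    speckle = gaussian_filter(rng.normal(0.0, 1.0, (height, width)), 1.5)
    speckle *= 14.0 / max(speckle.std(), 1e-12)
    tissue = np.stack(
        [215.0 * falloff, 95.0 * falloff, 45.0 * falloff], axis=-1
    )
    tissue += speckle[..., None] * np.array([1.0, 0.55, 0.3])
    img[inside] = tissue[inside]

    # optic disc: bright blob offset from the retina center
    disc_angle = rng.uniform(0, 2 * math.pi)
    disc_dist = rng.uniform(0.15, 0.4) * circle.r
    disc_cx = circle.cx + disc_dist * math.cos(disc_angle)
    disc_cy = circle.cy + disc_dist * math.sin(disc_angle)
    disc_r = 0.22 * circle.r
    dd = np.hypot(xx - disc_cx, yy - disc_cy) / disc_r
    blob = np.clip(1.0 - dd**2, 0.0, 1.0)
    disc_color = np.array([245.0, 210.0, 150.0])
    img[inside] += (blob[..., None] * (disc_color - tissue))[inside]

    # vessels: dark curves random-walking from the optic disc outward
    vessel_color = np.array([95.0, 25.0, 18.0])
    vessel_layer = img.copy()
    for _ in range(n_vessels):
        angle = rng.uniform(0, 2 * math.pi)
        half_width = rng.uniform(0.012, 0.028) * circle.r
        x, y = disc_cx, disc_cy
        pts = []
        curvature = rng.normal(0.0, 0.08)
        for _step in range(int(2.2 * circle.r)):
            angle += curvature + rng.normal(0.0, 0.05)
            x += math.cos(angle)
            y += math.sin(angle)
            if math.hypot(x - circle.cx, y - circle.cy) > 0.92 * circle.r:
                break
            pts.append((x, y))
        if pts:
            _stamp_polyline(vessel_layer, np.array(pts), half_width, vessel_color)
    img[inside] = vessel_layer[inside]

    img = np.clip(img, 0, 255).astype(np.uint8)

    red = img[:, :, 0].astype(np.float64)
    mean_in = red[inside].mean()
    mean_out = red[~inside].mean() if (~inside).any() else 0.0
    if mean_out > 0 and mean_in / mean_out < contrast:
        raise ValueError(
            f"scene violates the contrast invariant: {mean_in:.1f} vs {mean_out:.1f}"
        )
    return SyntheticScene(img, circle, seed)


def _motion_transform(
    circle: Circle, shift: tuple[float, float], rot_rad: float
) -> Homography:
    """Scene -> frame map: rotation about the retina center, then a shift."""
    c, s = math.cos(rot_rad), math.sin(rot_rad)
    cx, cy = circle.cx, circle.cy
    rot = np.array(
        [
            [c, -s, cx - c * cx + s * cy],
            [s, c, cy - s * cx - c * cy],
            [0, 0, 1],
        ]
    )
    trans = np.eye(3)
    trans[0, 2], trans[1, 2] = shift
    return Homography(trans @ rot)


def make_sequence(
    scene: SyntheticScene,
    n_frames: int,
    max_shift: float = 30.0,
    max_rot_deg: float = 5.0,
    illum_jitter: float = 0.0,
    seed: int = 0,
    source_id: str = "synthetic",
) -> SyntheticSequence:
    """Derive a small-motion sequence from a scene.

    Frame 0 is the scene itself. Frame ``i`` applies a random rotation about
    the retina center (<= ``max_rot_deg``) and a random shift (<=
    ``max_shift`` per axis), then scales intensity by a factor drawn from
    ``[1 - illum_jitter, 1 + illum_jitter]``. Ground-truth boxes and
    homographies are recorded exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if max_shift < 0 or max_rot_deg < 0 or illum_jitter < 0:
        raise ValueError("motion and jitter bounds must be non-negative")
    h, w = scene.image.shape[:2]
    c = scene.circle
    if (
        c.cx - c.r - max_shift < 0
        or c.cy - c.r - max_shift < 0
        or c.cx + c.r + max_shift > w
        or c.cy + c.r + max_shift > h
    ):
        raise ValueError("max_shift can push the retina off-frame")

    rng = np.random.default_rng(seed)
    frames = [Frame(scene.image.copy(), source_id=source_id, index=0)]
    gt_boxes = [circle_to_bbox(c, w, h)]
    gt_homographies = [Homography.identity()]
    illumination = [1.0]

    for i in range(1, n_frames):
        shift = tuple(rng.uniform(-max_shift, max_shift, size=2))
        rot = math.radians(rng.uniform(-max_rot_deg, max_rot_deg))
        to_frame = _motion_transform(c, shift, rot)  # scene -> frame i
        to_scene = to_frame.inverse()  # frame i -> scene (= frame 0)
        warped = warp(
            scene.image.astype(np.float64),
            inverse_map=ProjectiveTransform(matrix=to_scene.h),
            order=1,
            cval=0.0,
            preserve_range=True,
        )
        factor = 1.0 + (rng.uniform(-illum_jitter, illum_jitter) if illum_jitter else 0.0)
        warped = np.clip(np.floor(warped * factor + 0.5), 0, 255).astype(np.uint8)
        frames.append(Frame(warped, source_id=source_id, index=i))
        moved = Circle(c.cx + shift[0], c.cy + shift[1], c.r)
        gt_boxes.append(circle_to_bbox(moved, w, h))
        gt_homographies.append(to_scene)
        illumination.append(factor)

    return SyntheticSequence(frames, gt_boxes, gt_homographies, illumination)
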