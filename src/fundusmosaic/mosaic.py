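"""Two-stage mosaicing: keypoint registration and feathering blending.

Registration finds scale-space keypoints described with root-SIFT (L1
normalization followed by an element-wise square root, giving unit-L2
descriptors), matches them with a Lowe ratio test, and estimates a robust
planar homography with RANSAC. The keypoint stage is a plain
``Frame -> KeypointSet`` contract so a learned detector can be plugged in.

Blending feathers the two warped images across their overlap: each pixel's
weight is proportional to the Euclidean distance to the nearest pixel of the
*other* image outside the overlap, so seams fade smoothly. A sequence is
mosaiced incrementally — the first frame is the base referential, each
following frame registers against the previous one, the pairwise
homographies are composed, and the canvas grows to the union of warped
extents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial.distance import cdist
from skimage.color import rgb2gray
from skimage.feature import SIFT
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, warp

from .geometry import Frame, Homography

__all__ = [
    "KeypointSet",
    "MatchSet",
    "BlendField",
    "MosaicResult",
    "MosaicParams",
    "HomographyEstimate",
    "InsufficientMatchesError",
    "EstimationError",
    "detect_and_describe",
    "match_descriptors",
    "estimate_homography",
    "warp_to_reference",
    "compute_blend_weights",
    "blend",
    "mosaic_sequence",
]

logger = logging.getLogger(__name__)


class InsufficientMatchesError(ValueError):
    """Fewer than the 4 correspondences needed for a homography."""


class EstimationError(RuntimeError):
    """RANSAC failed to fit a homography (degenerate configuration)."""


@dataclass
class KeypointSet:
    """Interest-point locations (x, y) with unit-L2 root-SIFT descriptors."""

    locations: np.ndarray  # (N, 2) float, (x, y)
    descriptors: np.ndarray  # (N, 128) float, each with L2 norm 1
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.locations)

    @classmethod
    def empty(cls, source_id: str = "") -> "KeypointSet":
        return cls(np.empty((0, 2)), np.empty((0, 128)), source_id)


@dataclass
class MatchSet:
    """Correspondences: (base index, following index, descriptor distance)."""

    pairs: list[tuple[int, int, float]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class HomographyEstimate:
    homography: Homography
    n_inliers: int
    rms: float  # inlier reprojection RMS, px


@dataclass
class BlendField:
    """Masks, distances, and feathering weights of a two-image blend.

    ``R`` is the overlap ``m1 AND m2``; ``d_i`` is the Euclidean distance to
    the nearest pixel of image ``i`` *outside* the overlap; weights satisfy
    ``w1 + w2 = 1`` wherever both masks are set.
    """

    m1: np.ndarray
    m2: np.ndarray
    R: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    w1: np.ndarray
    w2: np.ndarray


@dataclass
class MosaicParams:
    ratio: float = 0.8
    ransac_threshold: float = 3.0
    min_inliers: int = 10
    seed: int = 0


@dataclass
class MosaicResult:
    """Final mosaic canvas with per-input homographies to the base referential.

    ``homographies[i]`` maps input ``i`` coordinates into base-image (input 0)
    coordinates; entry 0 is the identity, skipped inputs hold ``None``.
    ``offset`` is the (dx, dy) translation from base coordinates to canvas
    coordinates (the canvas can extend left/above the base image).
    """

    canvas: np.ndarray
    valid_mask: np.ndarray
    homographies: list[Homography | None]
    offset: tuple[int, int] = (0, 0)


def _to_gray_u8(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 3:
        return (rgb2gray(pixels) * 255).astype(np.uint8)
    return pixels


def detect_and_describe(img: Frame | np.ndarray) -> KeypointSet:
    """Scale-space keypoints with root-SIFT descriptors.

    Raw SIFT descriptors are L1-normalized and square-rooted element-wise,
    which makes their L2 norm exactly 1; Euclidean distance between such
    descriptors approximates the Hellinger kernel on the originals.
    A featureless (e.g. constant) image yields an empty set.
    """
    if isinstance(img, Frame):
        pixels, source_id = img.pixels, img.source_id
    else:
        pixels, source_id = np.asarray(img), ""
    gray = _to_gray_u8(pixels)
    extractor = SIFT()
    try:
        extractor.detect_and_extract(gray)
    except RuntimeError:  # SIFT raises when it finds no features
        return KeypointSet.empty(source_id)
    if extractor.keypoints is None or len(extractor.keypoints) == 0:
        return KeypointSet.empty(source_id)
    locations = extractor.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    desc = extractor.descriptors.astype(np.float64)
    l1 = desc.sum(axis=1, keepdims=True)
    l1[l1 == 0] = 1.0
    root = np.sqrt(desc / l1)
    return KeypointSet(locations, root, source_id)


def match_descriptors(base: KeypointSet, following: KeypointSet, ratio: float = 0.8) -> MatchSet:
    """Nearest-neighbour matching with the Lowe ratio test.

    Each base descriptor is matched to its Euclidean nearest neighbour in
    ``following`` and kept iff best/second-best distance < ``ratio``. Every
    following keypoint appears in at most one pair (closest base wins).
    """
    if not (0 < ratio <= 1):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if len(base) == 0 or len(following) == 0:
        return MatchSet([])
    dists = cdist(base.descriptors, following.descriptors)
    best_j = dists.argmin(axis=1)
    best_d = dists[np.arange(len(base)), best_j]
    if dists.shape[1] >= 2:
        part = np.partition(dists, 1, axis=1)
        second_d = part[:, 1]
    else:
        second_d = np.full(len(base), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        keep = np.where(second_d > 0, best_d / second_d < ratio, best_d == 0)
    claimed: dict[int, tuple[int, float]] = {}
    for i in np.flatnonzero(keep):
        j, d = int(best_j[i]), float(best_d[i])
        if j not in claimed or d < claimed[j][1]:
            claimed[j] = (int(i), d)
    pairs = sorted((i, j, d) for j, (i, d) in claimed.items())
    return MatchSet(pairs)


def estimate_homography(
    m: MatchSet,
    base: KeypointSet,
    following: KeypointSet,
    residual_threshold: float = 3.0,
    seed: int = 0,
) -> HomographyEstimate:
    """RANSAC homography mapping following-image coordinates into the base.

    Raises :class:`InsufficientMatchesError` with fewer than 4 matches and
    :class:`EstimationError` on degenerate (e.g. collinear) configurations.
    """
    if len(m) < 4:
        raise InsufficientMatchesError(
            f"homography estimation needs >= 4 matches, got {len(m)}"
        )
    base_pts = np.array([base.locations[i] for i, _, _ in m.pairs])
    foll_pts = np.array([following.locations[j] for _, j, _ in m.pairs])
    try:
        model, inliers = ransac(
            (foll_pts, base_pts),
            ProjectiveTransform,
            min_samples=4,
            residual_threshold=residual_threshold,
            max_trials=2000,
            rng=seed,
        )
    except Exception as exc:  # pragma: no cover - skimage internal failures
        raise EstimationError(f"homography estimation failed: {exc}") from exc
    if model is None or inliers is None or inliers.sum() < 4:
        raise EstimationError("RANSAC found no consistent homography")
    matrix = model.params
    if not np.all(np.isfinite(matrix)) or abs(np.linalg.det(matrix)) < 1e-12:
        raise EstimationError("degenerate homography estimate")
    residuals = model.residuals(foll_pts[inliers], base_pts[inliers])
    rms = float(np.sqrt(np.mean(residuals**2)))
    return HomographyEstimate(Homography(matrix), int(inliers.sum()), rms)


def warp_to_reference(
    img: Frame | np.ndarray, h: Homography, canvas_w: int, canvas_h: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear warp onto a canvas; mask = 1 where source pixels land."""
    if canvas_w < 1 or canvas_h < 1:
        raise ValueError("canvas dimensions must be positive")
    pixels = img.pixels if isinstance(img, Frame) else np.asarray(img)
    inv = ProjectiveTransform(matrix=h.inverse().h)
    warped = warp(
        pixels.astype(np.float64),
        inverse_map=inv,
        output_shape=(canvas_h, canvas_w),
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    warped = np.clip(np.floor(warped + 0.5), 0, 255).astype(np.uint8)
    ones = np.ones(pixels.shape[:2], dtype=np.float64)
    mask = warp(
        ones, inverse_map=inv, output_shape=(canvas_h, canvas_w), order=0, cval=0.0
    )
    return warped, (mask > 0.5).astype(np.uint8)


def compute_blend_weights(m1: np.ndarray, m2: np.ndarray) -> BlendField:
    """Feathering weights over a shared canvas.

    With overlap ``R = m1 AND m2`` and ``d_i`` the Euclidean distance to the
    nearest pixel with ``m_i = 1`` outside ``R``::

        w1 = 0 where m1 = 0;  d2 / (d1 + d2) inside R;  1 elsewhere
        w2 = 0 where m2 = 0;  d1 / (d1 + d2) inside R;  1 elsewhere

    If an image is entirely contained in the overlap its distance is
    undefined; that image receives uniform weight 0.5 inside ``R`` (with a
    logged warning).
    """
    m1 = np.asarray(m1).astype(bool)
    m2 = np.asarray(m2).astype(bool)
    if m1.shape != m2.shape:
        raise ValueError(f"mask shapes differ: {m1.shape} vs {m2.shape}")
    R = m1 & m2
    s1 = m1 & ~R  # m1's exclusive territory
    s2 = m2 & ~R
    # distance_transform_edt measures distance to the nearest zero pixel
    d1 = distance_transform_edt(~s1) if s1.any() else np.full(m1.shape, np.nan)
    d2 = distance_transform_edt(~s2) if s2.any() else np.full(m2.shape, np.nan)

    w1 = np.zeros(m1.shape, dtype=np.float64)
    w2 = np.zeros(m2.shape, dtype=np.float64)
    w1[m1 & ~R] = 1.0
    w2[m2 & ~R] = 1.0
    if R.any():
        if not s1.any() or not s2.any():
            logger.warning(
                "an image is fully contained in the overlap; using uniform 0.5 weights"
            )
            w1[R] = 0.5
            w2[R] = 0.5
        else:
            total = d1[R] + d2[R]
            w1[R] = d2[R] / total
            w2[R] = d1[R] / total
    return BlendField(
        m1.astype(np.uint8), m2.astype(np.uint8), R.astype(np.uint8), d1, d2, w1, w2
    )


def blend(I1: np.ndarray, I2: np.ndarray, f: BlendField) -> np.ndarray:
    """Per-pixel weighted sum ``w1*I1 + w2*I2``, rounded to 8-bit."""
    I1 = np.asarray(I1)
    I2 = np.asarray(I2)
    if I1.shape != I2.shape:
        raise ValueError(f"image shapes differ: {I1.shape} vs {I2.shape}")
    w1, w2 = f.w1, f.w2
    if I1.ndim == 3:
        w1 = w1[..., None]
        w2 = w2[..., None]
    out = w1 * I1.astype(np.float64) + w2 * I2.astype(np.float64)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def _translation(dx: float, dy: float) -> Homography:
    t = np.eye(3)
    t[0, 2] = dx
    t[1, 2] = dy
    return Homography(t)


def mosaic_sequence(
    imgs: list[Frame], params: MosaicParams | None = None
) -> MosaicResult:
    """Incrementally mosaic a pre-normalized sequence.

    The first frame is the base referential. Each following frame is
    registered against the previous successfully registered frame; its
    pairwise homography is composed with the accumulated transform to reach
    the base referential. The canvas auto-grows to the union of warped
    extents and feathering blending is applied at each accretion. Frames
    failing registration are skipped with a warning (their homography slot
    holds ``None``).
    """
    if len(imgs) < 2:
        raise ValueError("mosaic_sequence requires at least 2 images")
    if params is None:
        params = MosaicParams()

    base = imgs[0]
    canvas = base.pixels.copy()
    valid = np.ones(base.pixels.shape[:2], dtype=np.uint8)
    offset = (0.0, 0.0)  # canvas coords = base coords + offset
    homographies: list[Homography | None] = [Homography.identity()]
    prev_kp = detect_and_describe(base)
    prev_h = Homography.identity()  # previous registered frame -> base

    for img in imgs[1:]:
        kp = detect_and_describe(img)
        pair_h = None
        if len(kp) and len(prev_kp):
            matches = match_descriptors(prev_kp, kp, params.ratio)
            try:
                est = estimate_homography(
                    matches, prev_kp, kp, params.ransac_threshold, seed=params.seed
                )
                if est.n_inliers >= params.min_inliers:
                    pair_h = est.homography
                else:
                    logger.warning(
                        "frame %s/%d: only %d inliers (< %d); skipping",
                        img.source_id, img.index, est.n_inliers, params.min_inliers,
                    )
            except (InsufficientMatchesError, EstimationError) as exc:
                logger.warning(
                    "frame %s/%d: registration failed (%s); skipping",
                    img.source_id, img.index, exc,
                )
        else:
            logger.warning(
                "frame %s/%d: no keypoints; skipping", img.source_id, img.index
            )
        if pair_h is None:
            homographies.append(None)
            continue

        h_to_base = prev_h.compose(pair_h)

        # warped extent of the newcomer, in base coordinates
        h_img, w_img = img.pixels.shape[:2]
        corners = np.array(
            [[0, 0], [w_img, 0], [w_img, h_img], [0, h_img]], dtype=float
        )
        warped_corners = h_to_base.apply(corners)
        # current canvas extent in base coordinates
        ch, cw = canvas.shape[:2]
        eps = 1e-6  # guard against floor(-1e-12) spuriously growing the canvas
        x0 = min(-offset[0], np.floor(warped_corners[:, 0].min() + eps))
        y0 = min(-offset[1], np.floor(warped_corners[:, 1].min() + eps))
        x1 = max(cw - offset[0], np.ceil(warped_corners[:, 0].max() - eps))
        y1 = max(ch - offset[1], np.ceil(warped_corners[:, 1].max() - eps))
        new_w, new_h = int(x1 - x0), int(y1 - y0)
        new_offset = (-x0, -y0)

        # shift the existing mosaic into the grown canvas
        sx = int(round(new_offset[0] - offset[0]))
        sy = int(round(new_offset[1] - offset[1]))
        grown = np.zeros((new_h, new_w, 3), dtype=np.uint8)
        grown_mask = np.zeros((new_h, new_w), dtype=np.uint8)
        grown[sy : sy + ch, sx : sx + cw] = canvas
        grown_mask[sy : sy + ch, sx : sx + cw] = valid

        to_canvas = _translation(*new_offset).compose(h_to_base)
        warped, m2 = warp_to_reference(img, to_canvas, new_w, new_h)
        fld = compute_blend_weights(grown_mask, m2)
        canvas = blend(grown, warped, fld)
        valid = (grown_mask | m2).astype(np.uint8)
        offset = new_offset

        homographies.append(h_to_base)
        prev_kp = kp
        prev_h = h_to_base

    if all(h is None for h in homographies[1:]):
        logger.warning("all following frames failed registration; single-image mosaic")
    return MosaicResult(
        canvas, valid, homographies, (int(round(offset[0])), int(round(offset[1])))
    )
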