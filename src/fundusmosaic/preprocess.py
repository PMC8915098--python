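"""Set-wise intensity normalization.

All frames of a set are rescaled so their mean intensities match the lowest
mean in the set: each image is multiplied by ``min_mean / own_mean``. This
removes frame-to-frame illumination flicker before detection and mosaicing.
Because the reference is a set statistic, the whole set must be available
before any output is produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Frame

__all__ = ["NormalizationContext", "mean_intensity", "normalize_set"]


@dataclass
class NormalizationContext:
    """Bookkeeping of a set normalization.

    Attributes
    ----------
    per_image_mean : list of float
        Mean intensity of each input image (8-bit units).
    min_mean : float
        Lowest of the per-image means; the common target mean.
    ratios : list of float
        ``min_mean / per_image_mean`` per image, each in (0, 1].
    """

    per_image_mean: list[float]
    min_mean: float
    ratios: list[float]


def mean_intensity(img: Frame | np.ndarray) -> float:
    """Arithmetic mean over all pixels and all channels, in [0, 255]."""
    pixels = img.pixels if isinstance(img, Frame) else np.asarray(img)
    if pixels.size == 0:
        raise ValueError("cannot compute mean intensity of an empty image")
    return float(pixels.mean(dtype=np.float64))


def _round_half_up_u8(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; half-up keeps the scaling monotone per pixel
    return np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8)


def normalize_set(
    imgs: list[Frame], per_channel: bool = False
) -> tuple[list[Frame], NormalizationContext]:
    """Scale every image of a set to the set's minimum mean intensity.

    Each output is ``round(ratio * input)`` with ``ratio = min_mean / own_mean``
    computed in float; rounding is half-up to uint8. By default the mean is
    taken jointly over all three channels and the scaling is uniform (hue
    preserved); with ``per_channel=True`` each channel is normalized
    independently and the context holds per-channel 3-tuples instead of
    scalars. Raises ``ValueError`` if the set is empty or an image (or
    channel) has zero mean.
    """
    if not imgs:
        raise ValueError("normalize_set requires at least one image")
    if per_channel:
        means = [tuple(f.pixels.mean(axis=(0, 1), dtype=np.float64)) for f in imgs]
        for i, m in enumerate(means):
            if min(m) == 0.0:
                raise ValueError(f"image {i} has a zero-mean channel; cannot normalize")
        min_mean = tuple(min(m[c] for m in means) for c in range(3))
        ratios = [tuple(min_mean[c] / m[c] for c in range(3)) for m in means]
        out = [
            Frame(
                _round_half_up_u8(f.pixels.astype(np.float64) * np.asarray(r)),
                source_id=f.source_id,
                index=f.index,
            )
            for f, r in zip(imgs, ratios)
        ]
        return out, NormalizationContext(means, min_mean, ratios)
    means = [mean_intensity(f) for f in imgs]
    for i, m in enumerate(means):
        if m == 0.0:
            raise ValueError(f"image {i} has zero mean intensity; cannot normalize")
    min_mean = min(means)
    ratios = [min_mean / m for m in means]
    out = [
        Frame(
            _round_half_up_u8(f.pixels.astype(np.float64) * r),
            source_id=f.source_id,
            index=f.index,
        )
        for f, r in zip(imgs, ratios)
    ]
    return out, NormalizationContext(means, min_mean, ratios)
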