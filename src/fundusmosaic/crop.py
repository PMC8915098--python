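"""Crop the detected retinal region and standardize the canvas.

The crop is centered on a black square canvas (default 400x400) without any
resampling, preserving the retina's original scale; oversized crops are
center-cropped. A percentage resize is provided for high-resolution
reference images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .geometry import BBox, Frame

__all__ = ["CroppedRetina", "crop_and_pad", "resize_percent"]

logger = logging.getLogger(__name__)


@dataclass
class CroppedRetina:
    """A retinal crop centered on a square canvas.

    ``offset`` is the (dx, dy) of the retained crop's top-left corner inside
    the canvas; ``source_bbox`` is the box the crop came from.
    """

    pixels: np.ndarray
    offset: tuple[int, int]
    source_bbox: BBox


def crop_and_pad(img: Frame, b: BBox, canvas_side: int = 400) -> CroppedRetina:
    """Cut ``b`` out of ``img`` and center it on a black square canvas.

    Crop pixels are never resampled. If the crop exceeds the canvas in a
    dimension, that dimension is center-cropped to ``canvas_side`` (with a
    logged warning) rather than downscaled.
    """
    if canvas_side < 1:
        raise ValueError("canvas_side must be >= 1")
    if b.x_max > img.width or b.y_max > img.height:
        raise ValueError(f"bbox {b.as_tuple()} exceeds image {img.width}x{img.height}")
    crop = img.pixels[b.y_min : b.y_max, b.x_min : b.x_max]

    ch, cw = crop.shape[:2]
    if ch > canvas_side or cw > canvas_side:
        logger.warning(
            "crop %dx%d exceeds canvas %d; center-cropping", cw, ch, canvas_side
        )
        y0 = max(0, (ch - canvas_side) // 2)
        x0 = max(0, (cw - canvas_side) // 2)
        crop = crop[y0 : y0 + min(ch, canvas_side), x0 : x0 + min(cw, canvas_side)]
        ch, cw = crop.shape[:2]

    canvas = np.zeros((canvas_side, canvas_side, 3), dtype=np.uint8)
    dy = (canvas_side - ch) // 2
    dx = (canvas_side - cw) // 2
    canvas[dy : dy + ch, dx : dx + cw] = crop
    return CroppedRetina(canvas, (dx, dy), b)


def resize_percent(img: Frame, pct: float) -> Frame:
    """Bilinear resize to ``pct`` percent of each dimension.

    Output dimensions are ``floor(dim * pct / 100)`` per side (a 2912-pixel
    side at 15% becomes 436). 100% is the identity on dimensions.
    """
    if not (0 < pct <= 100):
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    new_w = math.floor(img.width * pct / 100)
    new_h = math.floor(img.height * pct / 100)
    if new_w < 1 or new_h < 1:
        raise ValueError(f"resize to {pct}% collapses the image to zero size")
    if (new_w, new_h) == (img.width, img.height):
        return Frame(img.pixels.copy(), source_id=img.source_id, index=img.index)
    resized = Image.fromarray(img.pixels).resize((new_w, new_h), Image.BILINEAR)
    return Frame(np.asarray(resized), source_id=img.source_id, index=img.index)
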