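"""Edge enhancement for normalized radiographs.

Sharpening subtracts the discrete 4-neighbor Laplacian from the image, which
amplifies tooth contours; the median filter applied afterwards removes the
impulse noise sharpening amplifies while preserving those contours.  The
order (sharpen, then median) matters and is fixed by :func:`enhance`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidImageError, InvalidParameterError
from .raster import RasterImage

#: Canonical 4-neighbor discretization of the continuous Laplacian operator.
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


@dataclass
class EnhancementParams:
    strength: float = 1.0  # Laplacian subtraction weight, unitless
    window: int = 3  # median window side length, odd


def _require_gray(image: RasterImage) -> np.ndarray:
    if image.channels != 1:
        raise InvalidImageError("enhancement operates on single-channel images")
    return image.pixels


def laplacian(image: RasterImage) -> np.ndarray:
    """Signed discrete Laplacian response (not clamped), edge-replicated borders."""
    px = _require_gray(image).astype(np.float64)
    return ndimage.convolve(px, LAPLACIAN_KERNEL, mode="nearest")


def sharpen(image: RasterImage, strength: float = 1.0) -> RasterImage:
    """Laplacian sharpening: ``out = clamp(in - strength * laplacian(in))``.

    At ``strength=1`` this is convolution with ``[[0,-1,0],[-1,5,-1],[0,-1,0]]``.
    """
    if strength < 0:
        raise InvalidParameterError(f"strength must be >= 0, got {strength}")
    px = _require_gray(image)
    if strength == 0:
        return image.copy()
    out = px.astype(np.float64) - strength * laplacian(image)
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(out, image.modality)


def median_filter(image: RasterImage, window: int = 3) -> RasterImage:
    """Order-statistic filter: each pixel becomes the median of its window.

    ``window`` is the odd side length (>= 3) of the square neighborhood;
    borders are edge-replicated, so every output value is an element of the
    input neighborhood.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError(f"window must be an odd integer >= 3, got {window}")
    px = _require_gray(image)
    out = ndimage.median_filter(px, size=window, mode="nearest")
    return RasterImage(out.astype(np.uint8), image.modality)


def enhance(image: RasterImage, params: EnhancementParams | None = None) -> RasterImage:
    """Sharpen, then median-filter (in that order)."""
    params = params or EnhancementParams()
    return median_filter(sharpen(image, params.strength), params.window)
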