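"""Distortion-free normalization of radiographs to a 640x640 letterboxed frame.

The pipeline is: convert to grayscale with the broadcast luma weights
(0.299 R + 0.587 G + 0.114 B), strip black borders, rescale the longest side
to the target size with a single uniform factor, and pad the short side with
black to a square.  Every geometric step is recorded in a
:class:`GeometryTransform` so points in the normalized frame can be mapped
back onto the original raster within one pixel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import (
    DegenerateInputWarning,
    InvalidImageError,
    InvalidParameterError,
    InvalidStateError,
    OutOfContentWarning,
)
from .raster import RasterImage

#: Luma weights for red, green, blue.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

DEFAULT_TARGET_SIZE = 640
DEFAULT_INTENSITY_THRESHOLD = 10
DEFAULT_FRACTION_THRESHOLD = 0.99


@dataclass
class NormalizationParams:
    """Tunable knobs of :func:`normalize_image`.

    ``intensity_threshold`` / ``fraction_threshold`` define the black-border
    rule: a full row or column is border when more than ``fraction_threshold``
    of its pixels are at or below ``intensity_threshold``.
    """

    target_size: int = DEFAULT_TARGET_SIZE
    intensity_threshold: int = DEFAULT_INTENSITY_THRESHOLD
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD
    pad_fill: int = 0


@dataclass
class GeometryTransform:
    """Invertible record of the crop/scale/pad chain.

    Forward maps original-frame points to the normalized frame; ``inverse``
    undoes it.  ``scale`` is a single factor for both axes (no anisotropy).
    """

    crop_top: int
    crop_left: int
    scale: float
    pad_top: int
    pad_left: int
    original_height: int
    original_width: int
    content_height: int = 0
    content_width: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidParameterError("scale must be positive")

    def forward(self, x: float, y: float) -> tuple[float, float]:
        """Original-frame point -> normalized-frame point."""
        return (
            (x - self.crop_left) * self.scale + self.pad_left,
            (y - self.crop_top) * self.scale + self.pad_top,
        )

    def inverse(self, x: float, y: float) -> tuple[float, float]:
        """Normalized-frame point -> original-frame point (extrapolates freely)."""
        return (
            (x - self.pad_left) / self.scale + self.crop_left,
            (y - self.pad_top) / self.scale + self.crop_top,
        )

    def in_content(self, x: float, y: float) -> bool:
        """True when the normalized-frame point lies on image content, not padding."""
        return (
            self.pad_left <= x < self.pad_left + self.content_width
            and self.pad_top <= y < self.pad_top + self.content_height
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeometryTransform":
        return cls(**json.loads(text))


def to_grayscale(image: RasterImage) -> RasterImage:
    """Collapse an RGB raster to single-channel luma.

    Each output pixel is ``round(0.299 R + 0.587 G + 0.114 B)`` with
    round-half-away-from-zero, clamped to [0, 255].  Single-channel input is
    passed through unchanged.
    """
    if image.channels == 1:
        return image
    if image.channels != 3:
        raise InvalidImageError(f"expected 1 or 3 channels, got {image.channels}")
    rgb = image.pixels.astype(np.float64)
    gray = GRAY_WEIGHTS[0] * rgb[..., 0] + GRAY_WEIGHTS[1] * rgb[..., 1] + GRAY_WEIGHTS[2] * rgb[..., 2]
    out = np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(out, image.modality)


def detect_black_borders(
    image: RasterImage,
    intensity_threshold: int = DEFAULT_INTENSITY_THRESHOLD,
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD,
) -> tuple[int, int, int, int]:
    """Find the content rectangle after stripping dark frame borders.

    Strips, from each edge inward, every full row/column whose fraction of
    pixels ``<= intensity_threshold`` exceeds ``fraction_threshold``.
    Returns ``(top, left, height, width)``.  If the whole frame is dark the
    full frame is returned with a :class:`DegenerateInputWarning`.
    """
    if image.channels != 1:
        raise InvalidImageError("border detection requires a single-channel image")
    px = image.pixels
    dark = px <= intensity_threshold
    row_frac = dark.mean(axis=1)
    col_frac = dark.mean(axis=0)

    def _leading(fracs: np.ndarray) -> int:
        n = 0
        for f in fracs:
            if f > fraction_threshold:
                n += 1
            else:
                break
        return n

    top = _leading(row_frac)
    bottom = _leading(row_frac[::-1])
    left = _leading(col_frac)
    right = _leading(col_frac[::-1])
    h, w = px.shape
    if top + bottom >= h or left + right >= w:
        warnings.warn(
            "entire image satisfies the border-darkness rule; keeping the full frame",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return (0, 0, h, w)
    return (top, left, h - top - bottom, w - left - right)


def crop(image: RasterImage, rect: tuple[int, int, int, int]) -> RasterImage:
    """Extract the rectangle ``(top, left, height, width)``."""
    top, left, h, w = rect
    return RasterImage(image.pixels[top : top + h, left : left + w], image.modality)


def resize_longest_side(
    image: RasterImage, target: int = DEFAULT_TARGET_SIZE
) -> tuple[RasterImage, float]:
    """Uniformly rescale so the longest side equals ``target`` pixels.

    Uses area-averaging (``BOX``) when shrinking and bilinear interpolation
    when enlarging.  Returns the resized raster and the scale factor.
    """
    if target < 1:
        raise InvalidParameterError(f"target size must be >= 1, got {target}")
    h, w = image.height, image.width
    scale = target / max(h, w)
    if scale == 1.0:
        return image, 1.0
    if h >= w:
        new_h, new_w = target, max(1, round(w * scale))
    else:
        new_h, new_w = max(1, round(h * scale)), target
    resample = Image.Resampling.BOX if scale < 1 else Image.Resampling.BILINEAR
    resized = Image.fromarray(image.pixels).resize((new_w, new_h), resample=resample)
    return RasterImage(np.asarray(resized, dtype=np.uint8), image.modality), scale


def pad_to_square(
    image: RasterImage, target: int = DEFAULT_TARGET_SIZE, fill: int = 0
) -> tuple[RasterImage, tuple[int, int]]:
    """Letterbox to ``target x target``; content centered, extra pixel to bottom/right.

    Returns the padded raster and the ``(pad_top, pad_left)`` offsets.
    """
    h, w = image.height, image.width
    if h > target or w > target:
        raise InvalidStateError(
            f"image {h}x{w} exceeds target {target}; resize must run before padding"
        )
    pad_top = (target - h) // 2
    pad_left = (target - w) // 2
    if image.channels == 1:
        out = np.full((target, target), fill, dtype=np.uint8)
        out[pad_top : pad_top + h, pad_left : pad_left + w] = image.pixels
    else:
        out = np.full((target, target, image.channels), fill, dtype=np.uint8)
        out[pad_top : pad_top + h, pad_left : pad_left + w, :] = image.pixels
    return RasterImage(out, image.modality), (pad_top, pad_left)


def normalize_image(
    image: RasterImage, params: NormalizationParams | None = None
) -> tuple[RasterImage, GeometryTransform]:
    """Full normalization: grayscale -> border crop -> resize -> letterbox pad.

    Returns the standardized ``target x target`` single-channel raster and the
    composed :class:`GeometryTransform`.
    """
    params = params or NormalizationParams()
    orig_h, orig_w = image.height, image.width
    gray = to_grayscale(image)
    rect = detect_black_borders(gray, params.intensity_threshold, params.fraction_threshold)
    cropped = crop(gray, rect)
    resized, scale = resize_longest_side(cropped, params.target_size)
    padded, (pad_top, pad_left) = pad_to_square(resized, params.target_size, params.pad_fill)
    transform = GeometryTransform(
        crop_top=rect[0],
        crop_left=rect[1],
        scale=scale,
        pad_top=pad_top,
        pad_left=pad_left,
        original_height=orig_h,
        original_width=orig_w,
        content_height=resized.height,
        content_width=resized.width,
    )
    return padded, transform


def map_to_original(
    point: tuple[float, float], transform: GeometryTransform
) -> tuple[float, float]:
    """Map a normalized-frame point back onto the original raster.

    Points inside the letterbox padding are still mapped (by extrapolating the
    affine chain) but flagged with :class:`OutOfContentWarning`.
    """
    x, y = point
    if not transform.in_content(x, y):
        warnings.warn(
            f"point ({x}, {y}) lies in the padding, outside the image content",
            OutOfContentWarning,
            stacklevel=2,
        )
    return transform.inverse(x, y)


def write_normalized(
    image: RasterImage, transform: GeometryTransform, out_path: "str | Path"
) -> None:
    """Save a normalized PNG plus its JSON sidecar transform record."""
    from .raster import save_image

    out_path = Path(out_path)
    save_image(image, out_path)
    out_path.with_suffix(".transform.json").write_text(transform.to_json())
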