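"""Raster image container and file I/O for radiographs.

A :class:`RasterImage` is a thin wrapper around a ``uint8`` numpy array
(``(H, W)`` grayscale or ``(H, W, 3)`` RGB, channel order red-green-blue)
tagged with the radiographic modality it came from.  DICOM input is windowed
to 8 bit by min-max scaling of the stored pixel range before any further
processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidImageError


class Modality(str, Enum):
    """Radiograph type: panoramic, periapical, bitewing, or unknown."""

    PANO = "PANO"
    PA = "PA"
    BW = "BW"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, value: "str | Modality") -> "Modality":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


@dataclass
class RasterImage:
    """2-D intensity grid in [0, 255] with a modality tag.

    ``pixels`` must be ``uint8`` with shape ``(H, W)`` or ``(H, W, 3)``.
    """

    pixels: np.ndarray
    modality: Modality = Modality.UNKNOWN

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.ndim not in (2, 3):
            raise InvalidImageError(f"expected 2-D or 3-D pixel array, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise InvalidImageError(f"expected 1 or 3 channels, got {px.shape[2]}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) or np.issubdtype(px.dtype, np.floating):
                if px.size and (px.min() < 0 or px.max() > 255):
                    raise InvalidImageError("intensity values must lie in [0, 255]")
                px = px.astype(np.uint8)
            else:
                raise InvalidImageError(f"unsupported dtype {px.dtype}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidImageError("image must be at least 1x1")
        self.pixels = px
        self.modality = Modality.parse(self.modality)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else int(self.pixels.shape[2])

    def copy(self) -> "RasterImage":
        return RasterImage(self.pixels.copy(), self.modality)


def _dicom_to_uint8(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim == 3 and arr.shape[-1] not in (3,):
        raise InvalidImageError("multi-frame DICOM is not supported")
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    else:
        arr = np.zeros_like(arr)
    if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
        arr = 255.0 - arr
    return np.floor(arr + 0.5).clip(0, 255).astype(np.uint8)


def load_image(path: "str | Path", modality: "str | Modality" = Modality.UNKNOWN) -> RasterImage:
    """Load a PNG/JPEG (or single-frame DICOM) raster from disk."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return RasterImage(_dicom_to_uint8(path), Modality.parse(modality))
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB") if len(im.getbands()) >= 3 else im.convert("L")
        arr = np.asarray(im, dtype=np.uint8)
    return RasterImage(arr, Modality.parse(modality))


def save_image(image: RasterImage, path: "str | Path") -> None:
    """Write the raster to PNG/JPEG (format chosen from the extension)."""
    Image.fromarray(image.pixels).save(str(path))
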