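"""Ground-truthed synthetic dentition layouts and phantom radiographs.

The generator emulates the box geometry a tooth detector produces on a
panoramic radiograph: two dental arches mirrored about a midline, teeth
abutting outward from the midline with position-dependent widths (incisors
narrower than molars), a parabolic occlusal curve, optional missing teeth
(true gaps), deciduous overlays on their successors' slots, and seeded
Gaussian jitter on box centers.  Phantom radiographs add an exact black
border and salt-and-pepper noise so normalization and enhancement can be
verified against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detections import DentitionLayout, DetectionBox, ToothClass
from .errors import GenerationError, InvalidParameterError
from .numbering import (
    FDICode,
    NumberingParams,
    NumberingResult,
    all_fdi_codes,
    number_panoramic,
)
from .raster import Modality, RasterImage

#: Per-position tooth widths in pixels for the reference 1200 px frame
#: (positions 1..8: central/lateral incisor, canine, premolars, molars).
DEFAULT_TOOTH_WIDTHS = (28.0, 26.0, 30.0, 32.0, 32.0, 46.0, 44.0, 42.0)

ALL_PERMANENT = frozenset(10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9))
ALL_DECIDUOUS = frozenset(10 * q + p for q in (5, 6, 7, 8) for p in range(1, 6))


@dataclass(frozen=True)
class ArchSpec:
    """Parameters of a synthetic dentition layout with ground truth.

    ``present_permanent`` / ``present_deciduous`` are sets of two-digit FDI
    codes (ints).  ``jitter_sd`` is an absolute Gaussian sd in pixels applied
    to box centers; ``jitter_frac`` adds a relative component, sd =
    ``jitter_frac`` x the tooth's own slot width.  Widths are scaled by
    ``image_width / 1200`` from the reference table.
    """

    image_width: int = 1200
    image_height: int = 700
    arch_center_x: float | None = None  # default: frame center
    upper_arch_y: float | None = None  # default: 250/700 of the frame height
    lower_arch_y: float | None = None  # default: 450/700 of the frame height
    arch_curvature: float | None = None  # default: 60/700 of the frame height
    tooth_widths: tuple = DEFAULT_TOOTH_WIDTHS
    tooth_height: float | None = None  # default: 80/700 of the frame height
    deciduous_width_ratio: float = 0.85
    deciduous_height_ratio: float = 0.75
    deciduous_occlusal_shift: float = 0.35  # fraction of tooth_height toward the occlusal line
    present_permanent: frozenset = ALL_PERMANENT
    present_deciduous: frozenset = frozenset()
    jitter_sd: float = 0.0
    jitter_frac: float = 0.0
    width_jitter_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        # resolve frame-proportional geometry defaults
        defaults = {
            "arch_center_x": self.image_width / 2.0,
            "upper_arch_y": self.image_height * 250.0 / 700.0,
            "lower_arch_y": self.image_height * 450.0 / 700.0,
            "arch_curvature": self.image_height * 60.0 / 700.0,
            "tooth_height": self.image_height * 80.0 / 700.0,
        }
        for name, value in defaults.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, value)
        if self.jitter_sd < 0 or self.jitter_frac < 0:
            raise InvalidParameterError("jitter must be non-negative")
        if any(w <= 0 for w in self.tooth_widths) or len(self.tooth_widths) != 8:
            raise InvalidParameterError("tooth_widths must be 8 positive values")
        for code in self.present_permanent:
            c = FDICode.from_int(code)
            if c.is_deciduous:
                raise InvalidParameterError(f"{code} is not a permanent FDI code")
        for code in self.present_deciduous:
            if not FDICode.from_int(code).is_deciduous:
                raise InvalidParameterError(f"{code} is not a deciduous FDI code")

    @property
    def scale(self) -> float:
        return self.image_width / 1200.0

    def width_of(self, position: int) -> float:
        return self.tooth_widths[position - 1] * self.scale

    def width_priors(self) -> dict[int, float]:
        """Per-position expected widths in pixels, for gap inference."""
        return {p: self.width_of(p) for p in range(1, 9)}


def _slot_geometry(spec: ArchSpec, code: FDICode) -> tuple[float, float, float, float]:
    """Jitter-free box (x1, y1, x2, y2) of an FDI slot."""
    quadrant = code.quadrant if code.quadrant <= 4 else code.quadrant - 4
    pos = code.position
    side = -1.0 if quadrant in (1, 4) else 1.0  # image-left vs image-right
    upper = quadrant in (1, 2)
    w = spec.width_of(pos)
    inner = sum(spec.width_of(p) for p in range(1, pos))
    x_inner = spec.arch_center_x + side * inner
    x_outer = x_inner + side * w
    x1, x2 = sorted((x_inner, x_outer))
    half_span = sum(spec.width_of(p) for p in range(1, 9))
    t = (inner + w / 2) / half_span
    if upper:
        ycen = spec.upper_arch_y - spec.arch_curvature * t * t
    else:
        ycen = spec.lower_arch_y + spec.arch_curvature * t * t
    h = spec.tooth_height
    if code.is_deciduous:
        w_d = w * spec.deciduous_width_ratio
        h = h * spec.deciduous_height_ratio
        shift = spec.deciduous_occlusal_shift * spec.tooth_height
        ycen = ycen + shift if upper else ycen - shift
        cx = 0.5 * (x1 + x2)
        x1, x2 = cx - w_d / 2, cx + w_d / 2
    return x1, ycen - h / 2, x2, ycen + h / 2


def generate_layout(spec: ArchSpec) -> tuple[DentitionLayout, list[tuple[DetectionBox, FDICode]]]:
    """Realize a spec as a layout plus the ground-truth (box, code) list.

    Deterministic for a fixed seed; jitter is applied to box centers only
    (widths too, behind ``width_jitter_frac``).
    """
    rng = np.random.default_rng(spec.seed)
    truth: list[tuple[DetectionBox, FDICode]] = []
    present = {FDICode.from_int(c) for c in spec.present_permanent | spec.present_deciduous}
    for code in all_fdi_codes():
        if code not in present:
            continue
        x1, y1, x2, y2 = _slot_geometry(spec, code)
        if x1 < 0 or y1 < 0 or x2 > spec.image_width or y2 > spec.image_height:
            raise GenerationError(f"slot {code} overflows the {spec.image_width}x{spec.image_height} frame")
        w = x2 - x1
        sd = spec.jitter_sd + spec.jitter_frac * spec.width_of(code.position)
        if sd > 0:
            dx, dy = rng.normal(0.0, sd, size=2)
            x1, x2, y1, y2 = x1 + dx, x2 + dx, y1 + dy, y2 + dy
        if spec.width_jitter_frac > 0:
            dw = rng.normal(0.0, spec.width_jitter_frac * w)
            x1, x2 = x1 - dw / 2, x2 + dw / 2
        x1 = max(0.0, x1)
        y1 = max(0.0, y1)
        x2 = min(float(spec.image_width), x2)
        y2 = min(float(spec.image_height), y2)
        if x2 - x1 <= 1.0 or y2 - y1 <= 1.0:
            raise GenerationError(f"slot {code} does not fit the frame")
        cls = ToothClass.DECIDUOUS if code.is_deciduous else ToothClass.PERMANENT
        truth.append((DetectionBox(x1, y1, x2, y2, cls, 1.0), code))
    layout = DentitionLayout(
        Modality.PANO, spec.image_width, spec.image_height, [b for b, _ in truth]
    )
    return layout, truth


def presence_of(spec: ArchSpec) -> dict[FDICode, int]:
    """Ground-truth 52-slot presence table of a spec."""
    present = spec.present_permanent | spec.present_deciduous
    return {code: int(int(code) in present) for code in all_fdi_codes()}


def interior_missing_of(spec: ArchSpec) -> set[FDICode]:
    """Permanent codes absent at positions inward of the last present tooth.

    Distal (trailing) absences are not observable from coordinates alone and
    are excluded, matching the default numbering behaviour.
    """
    missing: set[FDICode] = set()
    for q in (1, 2, 3, 4):
        present_pos = [p for p in range(1, 9) if 10 * q + p in spec.present_permanent]
        if not present_pos:
            continue
        last = max(present_pos)
        missing.update(FDICode(q, p) for p in range(1, last) if p not in present_pos)
    return missing


def mixed_dentition_fixture() -> tuple[DentitionLayout, dict[FDICode, int]]:
    """Mixed-dentition worked example: a zero-jitter layout and its reference
    presence table.

    Permanent positions 1-7 are present in all four quadrants (third molars
    absent); deciduous 53, 55, 63, 65, 74, 75 and 85 overlay their present
    successors.
    """
    permanent = frozenset(10 * q + p for q in (1, 2, 3, 4) for p in range(1, 8))
    deciduous = frozenset({53, 55, 63, 65, 74, 75, 85})
    spec = ArchSpec(present_permanent=permanent, present_deciduous=deciduous, jitter_sd=0.0, seed=0)
    layout, _ = generate_layout(spec)
    return layout, presence_of(spec)


def generate_radiograph(
    spec: ArchSpec,
    border: int = 50,
    noise_salt_prob: float = 0.0,
) -> tuple[RasterImage, tuple[int, int, int, int]]:
    """Phantom radiograph: bright elliptical blobs on mid-gray, black-bordered.

    Returns the raster and the true content rectangle
    ``(top, left, height, width)`` for crop verification.  Salt-and-pepper
    noise (half 255, half 0) is confined to the content region; the border is
    exactly zero.  Deterministic for the spec's seed.
    """
    if border < 0:
        raise InvalidParameterError("border must be >= 0")
    layout, _ = generate_layout(spec)
    rng = np.random.default_rng(spec.seed + 1)
    h, w = spec.image_height, spec.image_width
    content = np.full((h, w), 90, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    for box in layout.boxes:
        cx, cy = box.cx, box.cy
        rx, ry = box.width / 2, box.height / 2
        mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        content[mask] = 210
    if noise_salt_prob > 0:
        u = rng.random((h, w))
        content[u < noise_salt_prob / 2] = 255
        content[(u >= noise_salt_prob / 2) & (u < noise_salt_prob)] = 0
    full = np.zeros((h + 2 * border, w + 2 * border), dtype=np.uint8)
    full[border : border + h, border : border + w] = content
    return RasterImage(full, Modality.PANO), (border, border, h, w)


def recovery_rate(
    layout: DentitionLayout,
    truth: list[tuple[DetectionBox, FDICode]],
    result: NumberingResult,
) -> float:
    """Fraction of ground-truth boxes whose assigned code matches the truth."""
    assigned = {id(a.box): a.code for a in result.assignments}
    correct = sum(1 for box, code in truth if assigned.get(id(box)) == code)
    return correct / len(truth) if truth else 1.0


def perturbation_benchmark(
    base_spec: ArchSpec,
    jitter_grid: list[float],
    n_reps: int,
    seed: int,
    params: NumberingParams | None = None,
) -> pd.DataFrame:
    """Code-recovery rate of panoramic numbering across center-jitter levels.

    ``jitter_grid`` values are fractions of each tooth's own slot width
    (Gaussian sd).  Returns one row per jitter level with the mean recovery
    over ``n_reps`` seeded replicates.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for level in jitter_grid:
        seeds = rng.integers(0, 2**31 - 1, size=n_reps)
        rates = []
        for s in seeds:
            spec = replace(base_spec, jitter_frac=float(level), seed=int(s))
            layout, truth = generate_layout(spec)
            result = number_panoramic(layout, params)
            rates.append(recovery_rate(layout, truth, result))
        rows.append({"jitter": float(level), "recovery": float(np.mean(rates)), "n_reps": n_reps})
    return pd.DataFrame(rows)
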