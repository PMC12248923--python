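"""FDI tooth numbering from detection boxes, with missing-tooth inference.

For panoramic images the dentition is split into four quadrants around the
occlusal center, positions are assigned within each quadrant from the
midline outward, inter-tooth gaps larger than a tolerance of the expected
tooth width are converted into skipped (missing) positions, and deciduous
teeth receive their second digit from the nearest permanent tooth along the
x-axis.  Periapical and bitewing images use simple sequential numbering.

FDI notation: the first digit is the quadrant (1-4 permanent, 5-8
deciduous, clockwise from the image upper-left), the second the position
from the midline (1 = central incisor, up to 8 permanent / 5 deciduous).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .detections import DentitionLayout, DetectionBox, ToothClass
from .errors import (
    DegenerateArchError,
    DegenerateInputWarning,
    InvalidParameterError,
    QuadrantOverflowError,
    WrongModalityError,
)
from .raster import Modality

PERMANENT_QUADRANTS = (1, 2, 3, 4)
DECIDUOUS_QUADRANTS = (5, 6, 7, 8)
MAX_PERMANENT_POSITION = 8
MAX_DECIDUOUS_POSITION = 5


@dataclass(frozen=True, order=True)
class FDICode:
    """Two-digit FDI tooth code: quadrant then position from the midline."""

    quadrant: int
    position: int

    def __post_init__(self) -> None:
        if self.quadrant not in range(1, 9):
            raise InvalidParameterError(f"quadrant must be 1..8, got {self.quadrant}")
        limit = MAX_DECIDUOUS_POSITION if self.quadrant >= 5 else MAX_PERMANENT_POSITION
        if self.position not in range(1, limit + 1):
            raise InvalidParameterError(
                f"position must be 1..{limit} in quadrant {self.quadrant}, got {self.position}"
            )

    @property
    def is_deciduous(self) -> bool:
        return self.quadrant >= 5

    def __str__(self) -> str:
        return f"{self.quadrant}{self.position}"

    def __int__(self) -> int:
        return 10 * self.quadrant + self.position

    @classmethod
    def from_int(cls, value: int) -> "FDICode":
        return cls(value // 10, value % 10)


def all_fdi_codes() -> list[FDICode]:
    """The 32 permanent + 20 deciduous codes in FDI enumeration order."""
    codes = [FDICode(q, p) for q in PERMANENT_QUADRANTS for p in range(1, 9)]
    codes += [FDICode(q, p) for q in DECIDUOUS_QUADRANTS for p in range(1, 6)]
    return codes


@dataclass
class ToothAssignment:
    """Binding of one detection box to an FDI code."""

    box: DetectionBox
    code: FDICode

    def __post_init__(self) -> None:
        deciduous_box = self.box.tooth_class == ToothClass.DECIDUOUS
        if deciduous_box != self.code.is_deciduous:
            raise InvalidParameterError(
                f"box class {self.box.tooth_class.value} inconsistent with code {self.code}"
            )


@dataclass
class NumberingParams:
    """Knobs of the panoramic numbering algorithm.

    ``expected_width_source`` selects the tooth-width model used for gap
    inference: the jaw-median detected width, or per-position pixel priors
    (``width_priors``, mapping position 1-8 to an expected width).
    ``gap_tolerance`` in (0, 1): a span counts as a gap when it exceeds
    ``(1 - gap_tolerance)`` times the expected width.
    """

    expected_width_source: str = "median_of_quadrant"  # or "per_position_prior"
    width_priors: dict[int, float] | None = None
    gap_tolerance: float = 0.5
    include_third_molars_in_gaps: bool = False
    midline_estimator: str = "mirror_symmetry"  # or "median_x", "mean_x"

    def __post_init__(self) -> None:
        if not 0.0 < self.gap_tolerance < 1.0:
            raise InvalidParameterError("gap_tolerance must lie in (0, 1)")
        if self.expected_width_source not in ("median_of_quadrant", "per_position_prior"):
            raise InvalidParameterError(
                f"unknown expected_width_source {self.expected_width_source!r}"
            )
        if self.expected_width_source == "per_position_prior" and not self.width_priors:
            raise InvalidParameterError("per_position_prior requires width_priors")
        if self.midline_estimator not in ("mirror_symmetry", "median_x", "mean_x"):
            raise InvalidParameterError(f"unknown midline_estimator {self.midline_estimator!r}")


@dataclass
class NumberingResult:
    """Assignments, inferred missing codes, and the 52-slot presence table."""

    assignments: list[ToothAssignment]
    missing: list[FDICode]
    arch_center: tuple[float, float]
    presence: dict[FDICode, int]
    unassigned: list[DetectionBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [a.code for a in self.assignments]
        if len(codes) != len(set(codes)):
            raise InvalidParameterError("duplicate FDI codes among assignments")
        if set(codes) & set(self.missing):
            raise InvalidParameterError("a code cannot be both assigned and missing")

    def code_of(self, box: DetectionBox) -> FDICode | None:
        for a in self.assignments:
            if a.box is box:
                return a.code
        return None


# ---------------------------------------------------------------------------
# arch geometry
# ---------------------------------------------------------------------------


def _split_jaws(boxes: list[DetectionBox]) -> tuple[float, float, int]:
    """Largest-gap split of sorted box y-centers.

    Returns (y_mid, largest_gap, split_index into the sorted order).
    """
    ys = np.sort(np.array([b.cy for b in boxes]))
    gaps = np.diff(ys)
    idx = int(np.argmax(gaps))
    return float(0.5 * (ys[idx] + ys[idx + 1])), float(gaps[idx]), idx + 1


def _mirror_midline(boxes: list[DetectionBox]) -> float:
    """Midline as the axis of best bilateral mirror symmetry of box centers.

    Cost of a candidate midline c = sum over boxes of the capped distance
    between the box center mirrored about c and the nearest box center.
    Coarse 1 px grid search, refined over exact pair midpoints so that a
    perfectly symmetric arch yields the exact midline.
    """
    cx = np.array(sorted(b.cx for b in boxes))
    if len(cx) == 1:
        return float(cx[0])
    widths = np.array([b.width for b in boxes])
    cap = 0.5 * float(np.median(widths))

    def cost(cands: np.ndarray) -> np.ndarray:
        mirrored = 2.0 * cands[:, None] - cx[None, :]  # (C, n)
        d = np.abs(mirrored[:, :, None] - cx[None, None, :]).min(axis=2)
        return np.minimum(d, cap).sum(axis=1)

    lo, hi = np.percentile(cx, [25.0, 75.0])
    if hi - lo < 1.0:
        lo, hi = float(cx.min()), float(cx.max())
    coarse = np.arange(lo, hi + 1.0, 1.0)
    c0 = float(coarse[int(np.argmin(cost(coarse)))])
    # refine with exact midpoints of center pairs near the coarse optimum
    mids = 0.5 * (cx[:, None] + cx[None, :]).ravel()
    fine = np.unique(mids[np.abs(mids - c0) <= 2.0])
    cands = np.concatenate([[c0], fine])
    c = float(cands[int(np.argmin(cost(cands)))])
    # matched-pair polish: pair each center with the nearest center to its
    # mirror image and take the median of pair midpoints, which averages out
    # center jitter while leaving an exactly symmetric arch untouched
    pair_cap = 0.75 * float(np.median(widths))
    for _ in range(2):
        target = 2.0 * c - cx
        j = np.abs(target[:, None] - cx[None, :]).argmin(axis=1)
        dist = np.abs(target - cx[j])
        kept = 0.5 * (cx + cx[j])[dist <= pair_cap]
        if kept.size >= max(3, len(cx) // 4):
            c = float(np.median(kept))
    return c


def estimate_arch_center(
    layout: DentitionLayout, params: NumberingParams | None = None
) -> tuple[float, float]:
    """Central point of the occlusal surface, dividing the dentition into quadrants.

    ``y_mid`` is the midpoint of the largest gap in sorted box y-centers
    (which falls between the two jaws on a panoramic image); ``x_mid`` is the
    configured midline estimator over box x-centers.  Raises
    :class:`DegenerateArchError` when only one jaw is present.
    """
    params = params or NumberingParams()
    boxes = layout.boxes
    if len(boxes) < 2:
        raise DegenerateArchError(f"need at least 2 boxes, got {len(boxes)}")
    y_mid, largest_gap, _ = _split_jaws(boxes)
    median_height = float(np.median([b.height for b in boxes]))
    if largest_gap < median_height:
        jaw = "upper" if np.mean([b.cy for b in boxes]) < layout.image_height / 2 else "lower"
        raise DegenerateArchError(
            f"all boxes appear to lie in the {jaw} jaw (largest y gap "
            f"{largest_gap:.1f} px < median box height {median_height:.1f} px)",
            jaw_found=jaw,
        )
    # midline from permanent boxes when available (deciduous overlays are
    # often one-sided and would bias a symmetry estimate)
    perm = [b for b in boxes if b.tooth_class == ToothClass.PERMANENT]
    ref = perm if perm else boxes
    if params.midline_estimator == "median_x":
        x_mid = float(np.median([b.cx for b in ref]))
    elif params.midline_estimator == "mean_x":
        x_mid = float(np.mean([b.cx for b in ref]))
    else:
        x_mid = _mirror_midline(ref)
    return (x_mid, y_mid)


def assign_quadrant(box: DetectionBox, center: tuple[float, float]) -> int:
    """Quadrant of a box center: clockwise from upper-left in image coordinates.

    Upper-left -> 1, upper-right -> 2, lower-right -> 3, lower-left -> 4;
    deciduous boxes add 4.  A center exactly on the midline goes left; one
    exactly on the occlusal line goes to the upper jaw.
    """
    x_mid, y_mid = center
    left = box.cx <= x_mid
    upper = box.cy <= y_mid
    if upper:
        q = 1 if left else 2
    else:
        q = 4 if left else 3
    if box.tooth_class == ToothClass.DECIDUOUS:
        q += 4
    return q


def order_positions(quadrant_boxes: list[DetectionBox], x_mid: float) -> list[DetectionBox]:
    """Sort one quadrant's boxes by distance from the midline (ties: cx ascending)."""
    return sorted(quadrant_boxes, key=lambda b: (abs(b.cx - x_mid), b.cx))


# ---------------------------------------------------------------------------
# gap inference
# ---------------------------------------------------------------------------


def _quadrant_spans(ordered: list[DetectionBox], x_mid: float) -> list[float]:
    """Empty-space widths along the outward axis: midline->first, then between boxes."""
    side = 1.0 if np.median([b.cx for b in ordered]) >= x_mid else -1.0

    def inner(b: DetectionBox) -> float:
        return (b.x1 - x_mid) if side > 0 else (x_mid - b.x2)

    def outer(b: DetectionBox) -> float:
        return (b.x2 - x_mid) if side > 0 else (x_mid - b.x1)

    spans = [max(0.0, inner(ordered[0]))]
    for prev, nxt in zip(ordered, ordered[1:]):
        spans.append(max(0.0, inner(nxt) - outer(prev)))
    return spans


def infer_missing_in_quadrant(
    ordered_boxes: list[DetectionBox],
    x_mid: float,
    params: NumberingParams | None = None,
    expected_width: float | None = None,
    repair_overflow: bool = True,
) -> tuple[list[int], list[int]]:
    """Assign positions to ordered boxes and infer skipped (missing) positions.

    Each span (midline to first box, then between consecutive boxes) is
    compared with the expected tooth width; spans exceeding
    ``(1 - gap_tolerance) * w*`` skip ``round(gap / w*)`` positions (with
    per-position priors, the skip count that best explains the span).
    Trailing positions up to 8 are appended to the missing list only when
    ``include_third_molars_in_gaps`` is set.

    If inferred positions would exceed 8, the weakest gaps (least empty space
    per skipped slot) are discarded until the layout fits; a quadrant holding
    more than 8 boxes is a genuine :class:`QuadrantOverflowError`.
    """
    params = params or NumberingParams()
    n = len(ordered_boxes)
    if n == 0:
        return [], []
    if n > MAX_PERMANENT_POSITION:
        raise QuadrantOverflowError(f"{n} boxes cannot fit the 8 positions of one quadrant")

    spans = _quadrant_spans(ordered_boxes, x_mid)
    gate = 1.0 - params.gap_tolerance
    use_prior = params.expected_width_source == "per_position_prior"
    priors = params.width_priors or {}
    w_median = expected_width if expected_width is not None else float(
        np.median([b.width for b in ordered_boxes])
    )

    def prior_width(pos: int) -> float:
        return float(priors.get(pos, w_median))

    def skips_for(gap: float, pos_prev: int) -> int:
        max_k = MAX_PERMANENT_POSITION - pos_prev - 1
        if max_k <= 0:
            return 0
        if use_prior:
            best_k, best_err = 0, abs(gap)
            cum = 0.0
            for k in range(1, max_k + 1):
                cum += prior_width(pos_prev + k)
                err = abs(gap - cum)
                if err < best_err:
                    best_k, best_err = k, err
            if best_k >= 1 and gap <= gate * prior_width(pos_prev + 1):
                best_k = 0
            return best_k
        w_star = w_median if w_median > 0 else 1.0
        if gap <= gate * w_star:
            return 0
        return min(max_k, max(1, int(round(gap / w_star))))

    def layout_positions(skips: list[int]) -> tuple[list[int], list[int]]:
        positions, missing = [], []
        pos = 0
        for i in range(n):
            k = skips[i]
            missing.extend(range(pos + 1, pos + 1 + k))
            pos = pos + k + 1
            positions.append(pos)
        return positions, missing

    # sequential pass: the skip count depends on the running position
    skips: list[int] = []
    pos = 0
    for i in range(n):
        k = skips_for(spans[i], pos)
        skips.append(k)
        pos += k + 1

    if pos > MAX_PERMANENT_POSITION:
        if not repair_overflow:
            raise QuadrantOverflowError(
                f"inferred positions reach {pos} (> 8) in this quadrant"
            )
        # discard the weakest gap evidence (least span width per skipped slot)
        while pos > MAX_PERMANENT_POSITION:
            candidates = [i for i in range(n) if skips[i] > 0]
            if not candidates:  # pragma: no cover - n <= 8 guarantees progress
                break
            weakest = min(candidates, key=lambda i: (spans[i] / skips[i], i))
            skips[weakest] -= 1
            pos -= 1

    positions, missing = layout_positions(skips)
    if params.include_third_molars_in_gaps:
        missing.extend(range(positions[-1] + 1, MAX_PERMANENT_POSITION + 1))
    return positions, missing


# ---------------------------------------------------------------------------
# deciduous teeth
# ---------------------------------------------------------------------------


def _deciduous_quadrant(box: DetectionBox, center: tuple[float, float]) -> int:
    """Deciduous quadrant from the box's own side of the midline and jaw."""
    x_mid, y_mid = center
    left = box.cx <= x_mid
    upper = box.cy <= y_mid
    if upper:
        return 5 if left else 6
    return 8 if left else 7


def assign_deciduous(
    deciduous_boxes: list[DetectionBox],
    permanent_assignments: list[ToothAssignment],
    center: tuple[float, float],
) -> tuple[list[ToothAssignment], list[DetectionBox]]:
    """Second digits for deciduous teeth from the nearest permanent tooth in x.

    The quadrant comes from the deciduous box's own side of the midline; the
    position is the nearest same-jaw permanent tooth's position clamped to 5,
    then de-duplicated so outward boxes take larger positions.  With no
    permanent teeth in the jaw the fallback is pure geometric ordering from
    the midline (with a warning).  Boxes that cannot receive a position
    (more than 5 per quadrant) are returned as unassigned.
    """
    x_mid, y_mid = center
    assignments: list[ToothAssignment] = []
    unassigned: list[DetectionBox] = []
    by_quadrant: dict[int, list[tuple[DetectionBox, int]]] = {}

    for box in deciduous_boxes:
        quadrant = _deciduous_quadrant(box, center)
        upper = box.cy <= y_mid
        jaw_perm = [
            a for a in permanent_assignments if (a.box.cy <= y_mid) == upper
        ]
        if jaw_perm:
            nearest = min(jaw_perm, key=lambda a: (abs(a.box.cx - box.cx), a.code.position))
            pos = min(nearest.code.position, MAX_DECIDUOUS_POSITION)
        else:
            warnings.warn(
                "no permanent teeth in this jaw; deciduous positions fall back to "
                "geometric ordering from the midline",
                DegenerateInputWarning,
                stacklevel=2,
            )
            pos = 0  # resolved by ordering below
        by_quadrant.setdefault(quadrant, []).append((box, pos))

    for quadrant, items in sorted(by_quadrant.items()):
        items = sorted(items, key=lambda t: (abs(t[0].cx - x_mid), t[0].cx))
        positions = [p for _, p in items]
        if all(p == 0 for p in positions):  # geometric fallback
            positions = list(range(1, len(items) + 1))
        # forward pass: strictly increasing outward
        for i in range(len(positions)):
            floor = positions[i - 1] + 1 if i else 1
            positions[i] = max(positions[i], floor)
        # backward pass: keep within the 5 deciduous slots
        for i in range(len(positions) - 1, -1, -1):
            ceil = MAX_DECIDUOUS_POSITION - (len(positions) - 1 - i)
            positions[i] = min(positions[i], ceil)
        for i in range(1, len(positions)):
            positions[i] = max(positions[i], positions[i - 1] + 1)
        for (box, _), pos in zip(items, positions):
            if 1 <= pos <= MAX_DECIDUOUS_POSITION:
                assignments.append(ToothAssignment(box, FDICode(quadrant, pos)))
            else:
                unassigned.append(box)
    return assignments, unassigned


# ---------------------------------------------------------------------------
# full pipelines
# ---------------------------------------------------------------------------


def presence_from_assignments(assignments: list[ToothAssignment]) -> dict[FDICode, int]:
    """52-slot presence table: 1 iff the code appears among the assignments."""
    assigned = {a.code for a in assignments}
    return {code: int(code in assigned) for code in all_fdi_codes()}


def presence_table(result: NumberingResult) -> dict[FDICode, int]:
    """Deterministic 52-entry code -> {0, 1} map for a numbering result."""
    return presence_from_assignments(result.assignments)


def number_panoramic(
    layout: DentitionLayout,
    params: NumberingParams | None = None,
    strict: bool = False,
) -> NumberingResult:
    """Full FDI numbering of a panoramic layout with missing-tooth inference.

    Pipeline: occlusal-center estimation -> quadrant split -> per-quadrant
    ordering and gap inference for permanent teeth -> deciduous assignment ->
    presence table.  With ``strict=False`` (default) a quadrant holding more
    than 8 permanent boxes leaves the outermost surplus unassigned instead of
    raising.
    """
    if layout.modality not in (Modality.PANO, Modality.UNKNOWN):
        raise WrongModalityError(f"number_panoramic applies to PANO layouts, got {layout.modality.value}")
    params = params or NumberingParams()
    center = estimate_arch_center(layout, params)
    x_mid, y_mid = center

    perm_boxes = layout.of_class(ToothClass.PERMANENT)
    dec_boxes = layout.of_class(ToothClass.DECIDUOUS)

    quadrant_groups: dict[int, list[DetectionBox]] = {q: [] for q in PERMANENT_QUADRANTS}
    for box in perm_boxes:
        quadrant_groups[assign_quadrant(box, center)].append(box)

    # anatomical capacity repair: a quadrant cannot hold more than 8 permanent
    # teeth, so when one overflows while its same-jaw neighbour has room, the
    # box nearest the midline (the likely side mis-split) is moved across
    for qa, qb in ((1, 2), (2, 1), (4, 3), (3, 4)):
        while (
            len(quadrant_groups[qa]) > MAX_PERMANENT_POSITION
            and len(quadrant_groups[qb]) < MAX_PERMANENT_POSITION
        ):
            innermost = min(quadrant_groups[qa], key=lambda b: abs(b.cx - x_mid))
            quadrant_groups[qa].remove(innermost)
            quadrant_groups[qb].append(innermost)

    assignments: list[ToothAssignment] = []
    missing: list[FDICode] = []
    unassigned: list[DetectionBox] = []
    for quadrant in PERMANENT_QUADRANTS:
        group = quadrant_groups[quadrant]
        if not group:
            continue
        ordered = order_positions(group, x_mid)
        if len(ordered) > MAX_PERMANENT_POSITION:
            if strict:
                raise QuadrantOverflowError(
                    f"quadrant {quadrant} holds {len(ordered)} boxes (> 8)"
                )
            unassigned.extend(ordered[MAX_PERMANENT_POSITION:])
            ordered = ordered[:MAX_PERMANENT_POSITION]
        upper = quadrant in (1, 2)
        jaw_boxes = [b for b in perm_boxes if (b.cy <= y_mid) == upper]
        jaw_width = float(np.median([b.width for b in jaw_boxes])) if jaw_boxes else None
        positions, miss = infer_missing_in_quadrant(
            ordered, x_mid, params, expected_width=jaw_width, repair_overflow=not strict
        )
        assignments.extend(
            ToothAssignment(box, FDICode(quadrant, pos)) for box, pos in zip(ordered, positions)
        )
        missing.extend(FDICode(quadrant, p) for p in miss)

    dec_assignments, dec_unassigned = assign_deciduous(dec_boxes, assignments, center)
    assignments.extend(dec_assignments)
    unassigned.extend(dec_unassigned)

    return NumberingResult(
        assignments=assignments,
        missing=missing,
        arch_center=center,
        presence=presence_from_assignments(assignments),
        unassigned=unassigned,
    )


def number_sequential(layout: DentitionLayout) -> list[tuple[DetectionBox, int]]:
    """Sequential numbering for periapical and bitewing layouts (indices from 1).

    PA: left to right by box center.  BW: rows split at the occlusal line
    (largest gap in y-centers, when that gap is at least the median box
    height), upper row first, each row left to right.
    """
    if layout.modality == Modality.PANO:
        raise WrongModalityError("number_sequential applies to PA/BW layouts, not PANO")
    boxes = layout.boxes
    if not boxes:
        return []
    if layout.modality == Modality.BW and len(boxes) >= 2:
        y_mid, largest_gap, _ = _split_jaws(boxes)
        median_height = float(np.median([b.height for b in boxes]))
        if largest_gap >= median_height:
            upper = sorted((b for b in boxes if b.cy <= y_mid), key=lambda b: b.cx)
            lower = sorted((b for b in boxes if b.cy > y_mid), key=lambda b: b.cx)
            ordered = upper + lower
        else:
            ordered = sorted(boxes, key=lambda b: b.cx)
    else:
        ordered = sorted(boxes, key=lambda b: b.cx)
    return [(box, i) for i, box in enumerate(ordered, start=1)]


def result_to_dict(result: NumberingResult) -> dict:
    """JSON-ready report: assignments, missing codes, presence, arch center."""
    return {
        "arch_center": list(result.arch_center),
        "assignments": [
            {
                "x1": a.box.x1,
                "y1": a.box.y1,
                "x2": a.box.x2,
                "y2": a.box.y2,
                "class": a.box.tooth_class.value,
                "code": str(a.code),
            }
            for a in result.assignments
        ],
        "missing": [str(c) for c in result.missing],
        "presence": {str(c): v for c, v in result.presence.items()},
        "unassigned": len(result.unassigned),
    }
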