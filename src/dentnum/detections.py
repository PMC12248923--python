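"""Tooth detection containers, YOLO label I/O, and dataset splitting.

Pixel coordinates are 0-based; boxes are half-open ``[x1, x2) x [y1, y2)`` so
areas and overlaps are consistent throughout the package.  The default class
id mapping is ``0 = permanent, 1 = deciduous`` and can be overridden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, LabelFormatError, LabelValidationError
from .raster import Modality


class ToothClass(str, Enum):
    PERMANENT = "permanent"
    DECIDUOUS = "deciduous"


DEFAULT_CLASS_MAP: dict[int, ToothClass] = {0: ToothClass.PERMANENT, 1: ToothClass.DECIDUOUS}


@dataclass
class DetectionBox:
    """One detected tooth: pixel corners, class, and confidence.

    ``(x1, y1)`` is the top-left corner; ground-truth annotations carry
    confidence 1.0.
    """

    x1: float
    y1: float
    x2: float
    y2: float
    tooth_class: ToothClass = ToothClass.PERMANENT
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise InvalidParameterError(
                f"degenerate box ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidParameterError(f"confidence must lie in [0, 1], got {self.confidence}")
        self.tooth_class = ToothClass(self.tooth_class)

    @property
    def cx(self) -> float:
        return 0.5 * (self.x1 + self.x2)

    @property
    def cy(self) -> float:
        return 0.5 * (self.y1 + self.y2)

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass
class DentitionLayout:
    """All tooth detections for one image frame.

    The boxes list may be empty (edentulous frame); downstream code must
    tolerate that.
    """

    modality: Modality
    image_width: int
    image_height: int
    boxes: list[DetectionBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.modality = Modality.parse(self.modality)
        for box in self.boxes:
            if box.x1 < 0 or box.y1 < 0 or box.x2 > self.image_width or box.y2 > self.image_height:
                raise InvalidParameterError(
                    f"box ({box.x1}, {box.y1}, {box.x2}, {box.y2}) exceeds the "
                    f"{self.image_width}x{self.image_height} frame"
                )

    def of_class(self, tooth_class: ToothClass) -> list[DetectionBox]:
        return [b for b in self.boxes if b.tooth_class == tooth_class]


def read_yolo_labels(
    path: "str | Path",
    image_width: int,
    image_height: int,
    class_map: dict[int, ToothClass] | None = None,
    modality: "str | Modality" = Modality.UNKNOWN,
) -> DentitionLayout:
    """Parse a YOLO label file (``class xc yc w h [conf]``, normalized).

    Corners are recovered as ``x1 = (xc - w/2) * W`` etc. and clipped to the
    frame; a missing confidence defaults to 1.0.
    """
    text = Path(path).read_text()
    return parse_yolo_labels(text, image_width, image_height, class_map, modality)


def parse_yolo_labels(
    text: str,
    image_width: int,
    image_height: int,
    class_map: dict[int, ToothClass] | None = None,
    modality: "str | Modality" = Modality.UNKNOWN,
) -> DentitionLayout:
    class_map = class_map if class_map is not None else DEFAULT_CLASS_MAP
    boxes: list[DetectionBox] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise LabelFormatError(f"line {lineno}: expected 5 or 6 fields, got {len(fields)}")
        try:
            cls_id = int(fields[0])
            xc, yc, w, h = (float(v) for v in fields[1:5])
            conf = float(fields[5]) if len(fields) == 6 else 1.0
        except ValueError as exc:
            raise LabelFormatError(f"line {lineno}: {exc}") from exc
        for name, value in (("xc", xc), ("yc", yc), ("w", w), ("h", h), ("conf", conf)):
            if not 0.0 <= value <= 1.0:
                raise LabelValidationError(
                    f"line {lineno}: {name}={value} outside the normalized range [0, 1]"
                )
        if cls_id not in class_map:
            raise LabelValidationError(f"line {lineno}: unknown class id {cls_id}")
        x1 = max(0.0, (xc - w / 2) * image_width)
        x2 = min(float(image_width), (xc + w / 2) * image_width)
        y1 = max(0.0, (yc - h / 2) * image_height)
        y2 = min(float(image_height), (yc + h / 2) * image_height)
        boxes.append(DetectionBox(x1, y1, x2, y2, class_map[cls_id], conf))
    return DentitionLayout(Modality.parse(modality), image_width, image_height, boxes)


def write_yolo_labels(
    layout: DentitionLayout,
    class_map: dict[int, ToothClass] | None = None,
    include_confidence: bool = False,
) -> str:
    """Serialize a layout to YOLO label text (inverse of :func:`read_yolo_labels`)."""
    class_map = class_map if class_map is not None else DEFAULT_CLASS_MAP
    inverse = {v: k for k, v in class_map.items()}
    lines = []
    for box in layout.boxes:
        xc = box.cx / layout.image_width
        yc = box.cy / layout.image_height
        w = box.width / layout.image_width
        h = box.height / layout.image_height
        parts = [str(inverse[box.tooth_class])] + [f"{v:.6f}" for v in (xc, yc, w, h)]
        if include_confidence:
            parts.append(f"{box.confidence:.6f}")
        lines.append(" ".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class SplitManifest:
    """Deterministic train/validation/test partition of item identifiers."""

    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "train": self.train, "validation": self.validation, "test": self.test},
            indent=2,
        )


def split_dataset(
    item_ids: list[str],
    seed: int,
    test_fraction: float = 0.2,
    validation_fraction: float = 0.3,
    group_key=None,
) -> SplitManifest:
    """Shuffled two-stage partition: test split first, then validation.

    ``test_fraction`` of all items go to test; of the remainder,
    ``validation_fraction`` go to validation and the rest (the remainder
    absorbs rounding) to training.  With the defaults, 100 items split
    56/24/20.  ``group_key`` optionally stratifies by a grouping function so
    each group is partitioned with the same fractions.
    """
    if len(item_ids) < 3:
        raise InvalidParameterError(f"need at least 3 items to split, got {len(item_ids)}")
    if group_key is not None:
        groups: dict = {}
        for item in item_ids:
            groups.setdefault(group_key(item), []).append(item)
        train, val, test = [], [], []
        for i, key in enumerate(sorted(groups, key=str)):
            members = groups[key]
            if len(members) < 3:
                train.extend(members)
                continue
            sub = split_dataset(members, seed + i, test_fraction, validation_fraction)
            train.extend(sub.train)
            val.extend(sub.validation)
            test.extend(sub.test)
        return SplitManifest(train, val, test, seed)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(item_ids))
    shuffled = [item_ids[i] for i in order]
    n = len(shuffled)
    n_test = int(round(test_fraction * n))
    remainder = n - n_test
    n_val = int(round(validation_fraction * remainder))
    test = shuffled[:n_test]
    validation = shuffled[n_test : n_test + n_val]
    train = shuffled[n_test + n_val :]
    return SplitManifest(train, validation, test, seed)
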