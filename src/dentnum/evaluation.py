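"""Detection and numbering evaluation: IoU matching, confusion counts,
precision/recall/F1/accuracy, AP and mAP, and presence-table agreement.

Matching is greedy one-to-one in descending prediction confidence; AP uses
all-point interpolation with the monotone precision envelope (an 11-point
mode is available).  Zero-denominator metrics are reported as 0 with a
:class:`ZeroDenominatorWarning` rather than raising, because empty quadrants
and edentulous frames legitimately occur.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detections import DentitionLayout, DetectionBox
from .errors import InvalidParameterError, SchemaError, ZeroDenominatorWarning


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN counts; TN is undefined for open-set detection."""

    tp: int
    fp: int
    fn: int
    tn: int = 0
    tn_defined: bool = False

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")


@dataclass
class MatchResult:
    """One-to-one pairing of predictions and ground truths above an IoU threshold."""

    pairs: list[tuple[DetectionBox, DetectionBox, float]]
    unmatched_pred: list[DetectionBox]
    unmatched_truth: list[DetectionBox]


def iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection over union under the half-open box convention."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    pred: Sequence[DetectionBox],
    truth: Sequence[DetectionBox],
    iou_threshold: float = 0.5,
    class_aware: bool = True,
) -> MatchResult:
    """Greedy confidence-ordered matching.

    Each prediction, in descending confidence order, takes the highest-IoU
    still-unmatched truth box of the same class (when ``class_aware``) with
    IoU at or above the threshold.
    """
    order = sorted(range(len(pred)), key=lambda i: (-pred[i].confidence, i))
    taken = [False] * len(truth)
    pairs, unmatched_pred = [], []
    for i in order:
        p = pred[i]
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truth):
            if taken[j]:
                continue
            if class_aware and p.tooth_class != t.tooth_class:
                continue
            v = iou(p, t)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            pairs.append((p, truth[best_j], best_iou))
        else:
            unmatched_pred.append(p)
    unmatched_truth = [t for j, t in enumerate(truth) if not taken[j]]
    return MatchResult(pairs, unmatched_pred, unmatched_truth)


def confusion_from_match(match: MatchResult) -> ConfusionCounts:
    """TP = matched pairs, FP = unmatched predictions, FN = unmatched truths."""
    return ConfusionCounts(
        tp=len(match.pairs),
        fp=len(match.unmatched_pred),
        fn=len(match.unmatched_truth),
        tn=0,
        tn_defined=False,
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", ZeroDenominatorWarning, stacklevel=3)
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn, "recall")


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall."""
    p, r = precision(c), recall(c)
    return _ratio(2 * p * r, p + r, "f1")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return _ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn, "accuracy")


def average_precision(
    match_flags: Sequence[bool],
    total_truths: int,
    method: str = "all_point",
) -> float:
    """Area under the precision-recall curve for a ranked prediction list.

    ``match_flags`` must be ordered by descending confidence; ``True`` marks
    a prediction matched to a truth box.  ``all_point`` integrates the
    monotone precision envelope over every recall change; ``eleven_point``
    averages the envelope at recalls 0.0, 0.1, ..., 1.0.  Zero truths make
    the metric undefined (NaN, with a warning).
    """
    if method not in ("all_point", "eleven_point"):
        raise InvalidParameterError(f"unknown AP method {method!r}")
    if total_truths <= 0:
        warnings.warn("AP undefined with zero ground truths", ZeroDenominatorWarning, stacklevel=2)
        return math.nan
    flags = np.asarray(match_flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recalls = tp / total_truths
    precisions = tp / (tp + fp)
    # monotone non-increasing precision envelope
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    if method == "eleven_point":
        pts = []
        for r in np.linspace(0.0, 1.0, 11):
            mask = recalls >= r - 1e-12
            pts.append(float(env[mask].max()) if mask.any() else 0.0)
        return float(np.mean(pts))
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recalls, env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = float(r)
    return float(ap)


def mean_ap(per_class_ap: Sequence[float]) -> float:
    """Arithmetic mean of per-class AP values."""
    if len(per_class_ap) == 0:
        raise InvalidParameterError("mean_ap requires at least one class AP")
    return float(np.mean(per_class_ap))


def presence_agreement(
    predicted: Mapping, reference: Mapping
) -> tuple[float, list]:
    """Fraction of the 52 presence slots where two tables agree, plus mismatches."""
    if set(predicted.keys()) != set(reference.keys()):
        raise SchemaError("presence tables do not cover the same code set")
    mismatches = [code for code in reference if predicted[code] != reference[code]]
    frac = 1.0 - len(mismatches) / len(reference)
    return frac, sorted(mismatches, key=str)


# ---------------------------------------------------------------------------
# dataset-level metrics
# ---------------------------------------------------------------------------


def _ranked_flags(
    frames: Iterable[tuple[Sequence[DetectionBox], Sequence[DetectionBox]]],
    iou_threshold: float,
) -> tuple[list[tuple[float, bool]], int]:
    scored: list[tuple[float, bool]] = []
    n_truth = 0
    for pred, truth in frames:
        n_truth += len(truth)
        match = match_detections(pred, truth, iou_threshold)
        matched_ids = {id(p) for p, _, _ in match.pairs}
        for p in pred:
            scored.append((p.confidence, id(p) in matched_ids))
    scored.sort(key=lambda t: -t[0])
    return scored, n_truth


def detection_metrics(
    frames: Sequence[tuple[DentitionLayout, DentitionLayout]],
    iou_threshold: float = 0.5,
) -> dict[str, float]:
    """Dataset summary with the conventional detection-report row names.

    ``frames`` pairs predicted and ground-truth layouts image by image.
    Precision/Recall/F1 are computed at ``iou_threshold``; mAP50 at IoU 0.5
    and mAP50~95 averaged over IoU 0.50:0.05:0.95, each as the class mean
    over the tooth classes present in the ground truth.
    """
    classes = sorted({b.tooth_class for _, t in frames for b in t.boxes}, key=lambda c: c.value)
    counts = ConfusionCounts(0, 0, 0)
    for pred_layout, truth_layout in frames:
        c = confusion_from_match(
            match_detections(pred_layout.boxes, truth_layout.boxes, iou_threshold)
        )
        counts = ConfusionCounts(counts.tp + c.tp, counts.fp + c.fp, counts.fn + c.fn)

    def class_ap(thr: float) -> list[float]:
        aps = []
        for cls in classes:
            per_frame = [
                (
                    [b for b in p.boxes if b.tooth_class == cls],
                    [b for b in t.boxes if b.tooth_class == cls],
                )
                for p, t in frames
            ]
            scored, n_truth = _ranked_flags(per_frame, thr)
            if n_truth == 0:
                continue
            aps.append(average_precision([f for _, f in scored], n_truth))
        return aps

    ap50 = class_ap(0.5)
    ap_range = []
    for thr in np.arange(0.5, 0.96, 0.05):
        ap_range.extend(class_ap(float(thr)))
    return {
        "Precision": precision(counts),
        "Recall": recall(counts),
        "mAP50": mean_ap(ap50) if ap50 else math.nan,
        "mAP50~95": float(np.mean(ap_range)) if ap_range else math.nan,
        "F1-score": f1(counts),
    }
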