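"""Detection evaluation: per-image MAE and IoU, class binning, summaries.

MAE averages the absolute differences of the four box coordinates
(x_min, y_min, x_max, y_max), i.e. n = 4 scalar terms per image. IoU is the
ratio of intersection to union area. Each image is binned by its IoU:
Successful (> 0.8), Acceptable (0.6 < IoU <= 0.8), Failed (<= 0.6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import BBox, bbox_area, bbox_intersection, bbox_union_area

__all__ = [
    "BIN_SUCCESSFUL",
    "BIN_ACCEPTABLE",
    "BIN_FAILED",
    "EvalRecord",
    "EvalSummary",
    "mae",
    "iou",
    "classify_iou",
    "summarize",
    "evaluate_detections",
]

BIN_SUCCESSFUL = "Successful"
BIN_ACCEPTABLE = "Acceptable"
BIN_FAILED = "Failed"
_BINS = (BIN_SUCCESSFUL, BIN_ACCEPTABLE, BIN_FAILED)


@dataclass
class EvalRecord:
    """Per-image scores; ``mae`` is None for a missed detection."""

    image_id: str
    mae: float | None
    iou: float
    bin: str


@dataclass
class EvalSummary:
    """Aggregate in the shape of a per-class results table.

    ``per_bin`` maps bin name to a dict with keys ``count``, ``relative``
    (percent, 2-decimal), ``mean_mae`` and ``mean_iou`` (None when empty).
    Global statistics use the sample (n-1) standard deviation; records
    without a prediction are excluded from MAE aggregates but counted in
    bin frequencies.
    """

    per_bin: dict[str, dict]
    mean_mae: float | None
    std_mae: float | None
    mean_iou: float
    std_iou: float
    n_records: int
    n_missing: int


def mae(gt: BBox, pred: BBox) -> float:
    """Mean absolute error over the 4 box coordinates, in pixels."""
    diffs = [abs(g - p) for g, p in zip(gt.as_tuple(), pred.as_tuple())]
    return sum(diffs) / 4.0


def iou(a: BBox, b: BBox) -> float:
    """Intersection area over union area; 0 for disjoint boxes."""
    inter = bbox_intersection(a, b)
    if inter is None:
        return 0.0
    return bbox_area(inter) / bbox_union_area(a, b)


def classify_iou(v: float) -> str:
    """Bin an IoU value: Successful > 0.8 >= Acceptable > 0.6 >= Failed."""
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"IoU must be in [0, 1], got {v}")
    if v > 0.8:
        return BIN_SUCCESSFUL
    if v > 0.6:
        return BIN_ACCEPTABLE
    return BIN_FAILED


def _mean_std(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    m = sum(values) / len(values)
    if len(values) < 2:
        return m, 0.0
    var = sum((v - m) ** 2 for v in values) / (len(values) - 1)
    return m, math.sqrt(var)


def summarize(records: list[EvalRecord]) -> EvalSummary:
    """Per-bin counts/means plus global mean +/- sample std of MAE and IoU."""
    if not records:
        raise ValueError("summarize requires at least one record")
    per_bin: dict[str, dict] = {}
    for b in _BINS:
        rs = [r for r in records if r.bin == b]
        maes = [r.mae for r in rs if r.mae is not None]
        ious = [r.iou for r in rs]
        per_bin[b] = {
            "count": len(rs),
            "relative": round(100.0 * len(rs) / len(records), 2),
            "mean_mae": sum(maes) / len(maes) if maes else None,
            "mean_iou": sum(ious) / len(ious) if ious else None,
        }
    all_maes = [r.mae for r in records if r.mae is not None]
    all_ious = [r.iou for r in records]
    mean_mae, std_mae = _mean_std(all_maes)
    mean_iou, std_iou = _mean_std(all_ious)
    return EvalSummary(
        per_bin=per_bin,
        mean_mae=mean_mae,
        std_mae=std_mae,
        mean_iou=mean_iou,
        std_iou=std_iou,
        n_records=len(records),
        n_missing=sum(1 for r in records if r.mae is None),
    )


def evaluate_detections(
    gt: dict[str, BBox], pred: dict[str, BBox | None]
) -> list[EvalRecord]:
    """Score predictions against ground truth, one record per annotated image.

    A missing or ``None`` prediction scores IoU 0 (bin Failed) with MAE
    undefined.
    """
    records = []
    for image_id, gt_box in sorted(gt.items()):
        p = pred.get(image_id)
        if p is None:
            records.append(EvalRecord(image_id, None, 0.0, BIN_FAILED))
        else:
            v = iou(gt_box, p)
            records.append(EvalRecord(image_id, mae(gt_box, p), v, classify_iou(v)))
    return records
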