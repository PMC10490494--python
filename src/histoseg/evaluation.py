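"""Pixel-level segmentation metrics.

Foreground (nucleus/tumor) is the positive class. From the pixel
confusion counts TP/FP/FN/TN the five standard metrics are

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * recall * precision / (recall + precision)
    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    IoU       = TP / (TP + FP + FN)

Any metric whose denominator is zero is *undefined* and reported as
``None`` — never silently 0 or 1 — and undefined values are excluded
from aggregate means. F1 and IoU are algebraically tied:
F1 = 2*IoU/(1+IoU) whenever both are defined.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidParameterError, ValidationError

METRIC_NAMES = ("accuracy", "recall", "precision", "f1", "iou")


@dataclasses.dataclass
class ConfusionCounts:
    """Pixel confusion counts; foreground = positive."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclasses.dataclass
class MetricReport:
    """The five metrics; ``None`` marks an undefined (0/0) value."""

    accuracy: Optional[float]
    recall: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    iou: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/FN/TN between a predicted and a ground-truth mask."""
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Evaluate the five metrics exactly from confusion counts."""
    if min(c.TP, c.FP, c.FN, c.TN) < 0:
        raise InvalidParameterError("confusion counts must be non-negative")
    if c.total == 0:
        raise InvalidParameterError("no pixels to evaluate")
    precision = _ratio(c.TP, c.TP + c.FP)
    recall = _ratio(c.TP, c.TP + c.FN)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * recall * precision / (recall + precision)
    accuracy = (c.TP + c.TN) / c.total
    iou = _ratio(c.TP, c.TP + c.FP + c.FN)
    return MetricReport(accuracy=accuracy, recall=recall, precision=precision, f1=f1, iou=iou)


def _aggregate_mean(reports: Sequence[MetricReport]) -> MetricReport:
    """Unweighted mean per metric over the reports where it is defined."""
    values: dict[str, Optional[float]] = {}
    for name in METRIC_NAMES:
        defined = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        values[name] = float(np.mean(defined)) if defined else None
    return MetricReport(**values)


def evaluate_dataset(
    preds: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    mode: str = "per_image",
) -> tuple[list[MetricReport], MetricReport]:
    """Evaluate aligned mask lists.

    ``per_image`` returns one report per pair plus the unweighted mean of
    defined values; ``pooled`` sums the confusion counts over all pairs
    first and returns that single report (per-image list then holds the
    per-pair reports too, for inspection).
    """
    if len(preds) != len(truths):
        raise ValidationError(f"{len(preds)} predictions vs {len(truths)} truths")
    if mode not in ("per_image", "pooled"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    counts = [confusion_counts(p, t) for p, t in zip(preds, truths)]
    reports = [compute_metrics(c) for c in counts]
    if mode == "per_image":
        return reports, _aggregate_mean(reports)
    pooled = ConfusionCounts(
        TP=sum(c.TP for c in counts),
        FP=sum(c.FP for c in counts),
        FN=sum(c.FN for c in counts),
        TN=sum(c.TN for c in counts),
    )
    return reports, compute_metrics(pooled)


def write_report(
    ids: Sequence[str],
    reports: Sequence[MetricReport],
    aggregate: MetricReport,
    csv_path=None,
    json_path=None,
) -> None:
    """Write one row per image plus an aggregate row, as CSV and/or JSON."""
    if len(ids) != len(reports):
        raise ValidationError("ids and reports must align")
    rows = [{"id": i, **r.as_dict()} for i, r in zip(ids, reports)]
    rows.append({"id": "aggregate", **aggregate.as_dict()})
    if csv_path is not None:
        with Path(csv_path).open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["id", *METRIC_NAMES])
            writer.writeheader()
            for row in rows:
                writer.writerow(
                    {k: ("" if v is None else v) for k, v in row.items()}
                )
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2))
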