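"""Hard-mask evaluation: confusion counts, PA / IoU / precision / recall / F1.

The root class is the positive class. Conventions for degenerate counts
follow common segmentation-benchmark practice: if neither truth nor
prediction contains a positive pixel, the overlap metrics are 1 ("perfect
agreement on nothing there"); if the truth has positives but precision or
recall is 0/0, the undefined component is 0. For binary masks F1 equals
the Dice coefficient, so F1 = 2 IoU / (1 + IoU) identically.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_formats import LabelMask

AGGREGATION_MODES = ("micro", "macro")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class SegMetrics:
    pixel_accuracy: float
    iou: float
    precision: float
    recall: float
    f1: float
    mode: str = "micro"

    def scaled(self) -> dict:
        """Values x100, matching how segmentation papers print them."""
        return {
            k: round(v * 100.0, 2)
            for k, v in asdict(self).items()
            if isinstance(v, float)
        }


def _as_binary(mask, name: str) -> np.ndarray:
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    if data.ndim != 2:
        raise ValueError(f"{name} must be a 2-D mask, got shape {data.shape}")
    return data


def confusion_counts(pred, truth, positive_class: int = 1) -> ConfusionCounts:
    """Exact pixel counts of the binary confusion matrix."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"pred {p.shape} and truth {t.shape} differ in shape")
    pp = p == positive_class
    tp_ = t == positive_class
    tp = int(np.count_nonzero(pp & tp_))
    fp = int(np.count_nonzero(pp & ~tp_))
    fn = int(np.count_nonzero(~pp & tp_))
    tn = int(np.count_nonzero(~pp & ~tp_))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_ratio(num: int, den: int, empty_truth_and_pred: bool) -> float:
    if den == 0:
        return 1.0 if empty_truth_and_pred else 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, mode: str = "micro") -> SegMetrics:
    """PA, IoU, precision, recall and F1 from hard confusion counts."""
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    empty = (tp + fp + fn) == 0  # no positives anywhere
    pa = (tp + tn) / counts.total
    iou = _safe_ratio(tp, tp + fp + fn, empty)
    precision = _safe_ratio(tp, tp + fp, empty)
    recall = _safe_ratio(tp, tp + fn, empty)
    if precision + recall == 0:
        f1 = 1.0 if empty else 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return SegMetrics(
        pixel_accuracy=pa, iou=iou, precision=precision, recall=recall, f1=f1,
        mode=mode,
    )


def evaluate_dataset(pairs, mode: str = "micro") -> SegMetrics:
    """Aggregate metrics over (pred, truth) pairs.

    micro pools confusion counts before computing metrics; macro averages
    per-image metrics.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset needs at least one (pred, truth) pair")
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"mode must be one of {AGGREGATION_MODES}, got {mode!r}")
    counts = [confusion_counts(p, t) for p, t in pairs]
    if mode == "micro":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        return compute_metrics(pooled, mode="micro")
    per_image = [compute_metrics(c) for c in counts]
    fields = ("pixel_accuracy", "iou", "precision", "recall", "f1")
    means = {f: float(np.mean([getattr(m, f) for m in per_image])) for f in fields}
    return SegMetrics(**means, mode="macro")


def write_report(pairs, out_path, mode: str = "micro") -> SegMetrics:
    """Per-image rows + aggregate row, written as CSV and JSON side by side."""
    pairs = list(pairs)
    aggregate = evaluate_dataset(pairs, mode=mode)
    rows = []
    for i, (p, t) in enumerate(pairs):
        m = compute_metrics(confusion_counts(p, t))
        row = {"identifier": str(i), **{k: v for k, v in asdict(m).items() if k != "mode"}}
        rows.append(row)
    out_path = Path(out_path)
    fields = ["identifier", "pixel_accuracy", "iou", "precision", "recall", "f1"]
    with open(out_path.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
        writer.writerow({"identifier": f"aggregate_{mode}",
                         **{k: getattr(aggregate, k) for k in fields[1:]}})
    payload = {
        "per_image": rows,
        "aggregate": asdict(aggregate),
        "aggregate_x100": aggregate.scaled(),
    }
    out_path.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    return aggregate
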