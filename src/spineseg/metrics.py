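"""Overlap metrics for segmentation: dice, IoU, precision, recall.

Definitions (P1 = prediction, P2 = ground truth, both binary):

    DSC       = 2|P1 ∩ P2| / (|P1| + |P2|)
    IoU       = TP / (TP + FN + FP)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)

Empty-empty convention: when both masks are empty a prediction is vacuously
perfect, so every metric is defined as 1.  Multi-class reports are macro
averages over the classes present in the ground truth (per-scan vertebra
subsets vary, so averaging over a fixed class list would punish absent
classes).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def _as_binary(a) -> np.ndarray:
    a = np.asarray(a)
    return a.astype(bool)


def _check_pair(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    p1, p2 = _as_binary(p1), _as_binary(p2)
    if p1.shape != p2.shape:
        raise ValueError(f"mask shapes differ: {p1.shape} vs {p2.shape}")
    return p1, p2


def confusion_counts(p1, p2) -> ConfusionCounts:
    """Exact voxel tallies of prediction p1 against truth p2."""
    p1, p2 = _check_pair(p1, p2)
    tp = int(np.count_nonzero(p1 & p2))
    fp = int(np.count_nonzero(p1 & ~p2))
    fn = int(np.count_nonzero(~p1 & p2))
    tn = int(p1.size - tp - fp - fn)
    return ConfusionCounts(tp, fp, fn, tn)


def dice(p1, p2) -> float:
    p1, p2 = _check_pair(p1, p2)
    inter = int(np.count_nonzero(p1 & p2))
    total = int(np.count_nonzero(p1)) + int(np.count_nonzero(p2))
    return 1.0 if total == 0 else 2.0 * inter / total


def iou(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn + c.fp
    return 1.0 if denom == 0 else c.tp / denom


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return 1.0 if denom == 0 else c.tp / denom


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def binary_report(p1, p2) -> dict[str, float]:
    c = confusion_counts(p1, p2)
    return {"dice": dice(p1, p2), "iou": iou(c),
            "precision": precision(c), "recall": recall(c)}


def macro_report(pred, truth, classes=None) -> dict:
    """One-vs-rest metrics per class plus macro means.

    `classes` defaults to the nonzero labels present in the truth.  A class
    absent from both maps scores 1 on every metric and is flagged "absent";
    macro means run over the classes present in the truth.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"maps are misaligned: {pred.shape} vs {truth.shape}")
    if classes is None:
        classes = [int(k) for k in np.unique(truth) if k != 0]
    rows = []
    for k in classes:
        p1, p2 = pred == k, truth == k
        row = {"class": int(k), "absent": not p2.any(), **binary_report(p1, p2)}
        rows.append(row)
    present = [r for r in rows if not r["absent"]] or rows
    macro = {m: float(np.mean([r[m] for r in present]))
             for m in ("dice", "iou", "precision", "recall")}
    return {"per_class": rows, "macro": macro}


def write_report(rows: list[dict], macro: dict, csv_path, json_path) -> None:
    """CSV of per-scan/per-class rows (percent, 2 decimals) + JSON macro summary."""
    fields = ["scan_id", "class", "DSC", "IoU", "Precision", "Recall"]
    with open(csv_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for r in rows:
            w.writerow({
                "scan_id": r.get("scan_id", ""),
                "class": r.get("class", ""),
                "DSC": f"{100 * r['dice']:.2f}",
                "IoU": f"{100 * r['iou']:.2f}",
                "Precision": f"{100 * r['precision']:.2f}",
                "Recall": f"{100 * r['recall']:.2f}",
            })
    with open(json_path, "w") as fh:
        json.dump({"macro_percent": {k: round(100 * v, 2)
                                     for k, v in macro.items()}}, fh, indent=2)
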