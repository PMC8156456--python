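"""Confusion-matrix segmentation metrics with per-image table averaging.

Six measures per image: sensitivity, specificity, accuracy, Jaccard, Dice
and the Matthews correlation coefficient, computed from pixel tallies with
the lesion as the positive class.  Tables average metric values across
images (not pooled pixels); a pooled variant is exposed separately.

Degenerate conventions (empty positive class etc.): sensitivity with
TP+FN=0 is 1; Jaccard/Dice with an empty union are 1; MCC with any zero
factor under the root is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "evaluate_per_image",
    "METRIC_NAMES",
]

METRIC_NAMES = ("SEN", "SPE", "ACC", "JAC", "DIC", "MCC")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sen: float
    spe: float
    acc: float
    jac: float
    dic: float
    mcc: float

    def as_dict(self, percent: bool = False) -> dict:
        vals = [self.sen, self.spe, self.acc, self.jac, self.dic, self.mcc]
        if percent:
            vals = [round(100.0 * v, 2) for v in vals]
        return dict(zip(METRIC_NAMES, vals))


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {uniq[:10]}")
    return arr.astype(bool)


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    pred = _check_binary(pred_mask, "pred_mask")
    gt = _check_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, degenerate: float) -> float:
    return num / den if den > 0 else degenerate


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    if c.total <= 0:
        raise ValueError("empty confusion counts")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    sen = _ratio(tp, tp + fn, 1.0)
    spe = _ratio(tn, fp + tn, 1.0)
    acc = (tp + tn) / (tp + fn + tn + fp)
    jac = _ratio(tp, tp + fn + fp, 1.0)
    dic = _ratio(2 * tp, 2 * tp + fp + fn, 1.0)
    root = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(root) if root > 0 else 0.0
    return MetricsReport(sen=sen, spe=spe, acc=acc, jac=jac, dic=dic, mcc=float(mcc))


def evaluate_per_image(pred_masks, gt_masks, percent: bool = False) -> pd.DataFrame:
    """Per-image metric table with an unweighted 'mean' row appended."""
    pred_masks, gt_masks = list(pred_masks), list(gt_masks)
    if len(pred_masks) != len(gt_masks):
        raise ValueError(f"got {len(pred_masks)} predictions but {len(gt_masks)} ground truths")
    if not pred_masks:
        raise ValueError("no images to evaluate")
    rows = []
    for i, (p, g) in enumerate(zip(pred_masks, gt_masks)):
        rep = compute_metrics(confusion(p, g))
        rows.append({"image": str(i), **rep.as_dict(percent=percent)})
    df = pd.DataFrame(rows).set_index("image")
    df.loc["mean"] = df.mean(axis=0)
    return df


def pooled_metrics(pred_masks, gt_masks) -> MetricsReport:
    """Metrics of the pixel-pooled confusion matrix over all images."""
    total = ConfusionCounts(0, 0, 0, 0)
    for p, g in zip(pred_masks, gt_masks):
        c = confusion(p, g)
        total = ConfusionCounts(total.tp + c.tp, total.fp + c.fp,
                                total.tn + c.tn, total.fn + c.fn)
    return compute_metrics(total)
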