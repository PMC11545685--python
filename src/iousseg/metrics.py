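"""Pixel-wise segmentation metrics and per-vessel aggregation.

Frame-level evaluation counts the pixel confusion matrix between the
thresholded prediction and the ground-truth mask and derives Dice, IoU
(Jaccard), recall, precision and accuracy; AUC-ROC is computed rank-based
(Mann-Whitney with midrank ties) over the raw probability map. Aggregation
reports unweighted per-frame mean and sample standard deviation for each
vessel, in the column order Dice, IoU, Recall, Precision, Accuracy,
AUC-ROC.

Zero-denominator convention: when truth and prediction are both empty the
overlap metrics are vacuously 1; a ratio whose denominator is zero with a
non-empty counterpart (e.g. recall on an empty truth) is undefined and
reported as NaN, which aggregation skips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "confusion",
    "metrics_from_counts",
    "auc_roc",
    "evaluate_frame",
    "aggregate",
    "METRIC_ORDER",
]

METRIC_ORDER = ("dice", "iou", "recall", "precision", "accuracy", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsRecord:
    dice: float
    iou: float
    recall: float
    precision: float
    accuracy: float
    auc: float = float("nan")
    scope: str = "frame"
    vessel: str | None = None


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts between two binary masks."""
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError("pred and truth must share one grid")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int, vacuous: float = float("nan")) -> float:
    return num / den if den > 0 else vacuous


def metrics_from_counts(c: ConfusionCounts) -> MetricsRecord:
    """Dice, IoU, recall, precision and accuracy from confusion counts.

    Dice is the count form of 2|X∩Y|/(|X|+|Y|); both-empty masks agree
    vacuously (all overlap metrics 1), while a one-sided zero denominator
    yields NaN for the affected ratio only.
    """
    if min(c.tp, c.tn, c.fp, c.fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    both_empty = (c.tp + c.fp + c.fn) == 0
    return MetricsRecord(
        dice=1.0 if both_empty else _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        iou=1.0 if both_empty else _ratio(c.tp, c.tp + c.fn + c.fp),
        recall=1.0 if both_empty else _ratio(c.tp, c.tp + c.fn),
        precision=1.0 if both_empty else _ratio(c.tp, c.tp + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        scope="frame",
    )


def auc_roc(prob: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC over pixels, midrank tie handling.

    Returns NaN when the truth contains a single class, where the ROC
    curve is undefined.
    """
    t = _check_binary(truth, "truth").ravel()
    p = np.asarray(prob, dtype=np.float64).ravel()
    if p.shape != t.shape:
        raise ValueError("prob and truth must share one grid")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(p)
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_frame(
    prob: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
    vessel: str | None = None,
) -> MetricsRecord:
    """Full metric record for one probability map against its truth mask."""
    pred = (np.asarray(prob) >= threshold).astype(np.uint8)
    rec = metrics_from_counts(confusion(pred, truth))
    rec.auc = auc_roc(prob, truth)
    rec.vessel = vessel
    return rec


def aggregate(records: list[MetricsRecord]) -> pd.DataFrame:
    """Per-vessel mean ± sample SD over frames.

    One row per vessel; columns follow the reporting order Dice, IoU,
    Recall, Precision, Accuracy, AUC-ROC, each as ``<metric>_mean`` and
    ``<metric>_sd``. NaN (undefined) frame values are skipped; a single
    frame reports SD 0.
    """
    if not records:
        raise ValueError("no records to aggregate")
    rows = []
    df = pd.DataFrame([{
        "vessel": r.vessel if r.vessel is not None else "all",
        **{m: getattr(r, m) for m in METRIC_ORDER},
    } for r in records])
    for vessel, grp in df.groupby("vessel", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empties
            continue
        row = {"vessel": vessel, "n_frames": len(grp)}
        for m in METRIC_ORDER:
            vals = grp[m].dropna()
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    cols = ["vessel", "n_frames"] + [f"{m}_{s}" for m in METRIC_ORDER
                                     for s in ("mean", "sd")]
    return pd.DataFrame(rows, columns=cols)
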