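"""Per-class one-vs-rest evaluation metrics.

Each class in turn is treated as positive and all others as negative,
giving per-class counts Tp/Fn/Fp/Tn from which five standard criteria
are computed:

* accuracy        Acc = (Tp + Tn) / (Tp + Fn + Fp + Tn)
* sensitivity     Sn  = Tp / (Tp + Fn)
* specificity     Sp  = Tn / (Fp + Tn)
* precision       Pr  = Tp / (Tp + Fp)
* F1 score        F1  = 2 Pr Sn / (Pr + Sn)

A metric with a zero denominator is *undefined* and reported as NaN; the
"Average" row is the unweighted arithmetic mean over classes, skipping
undefined values (rather than silently counting them as zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import multilabel_confusion_matrix

METRICS = ("Acc", "Sn", "Sp", "Pr", "F1")


@dataclass
class ConfusionTally:
    """One-vs-rest counts per class: ``counts[cls] = (tp, fn, fp, tn)``."""

    classes: tuple[str, ...]
    counts: dict[str, tuple[int, int, int, int]]

    @property
    def n_samples(self) -> int:
        return sum(self.counts[self.classes[0]])


def tally(labels, predictions, classes=None) -> ConfusionTally:
    """One-vs-rest confusion counts for every class."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"labels ({labels.shape}) and predictions ({predictions.shape}) "
            "must have the same length"
        )
    if classes is None:
        classes = sorted(set(labels) | set(predictions))
    classes = tuple(str(c) for c in classes)
    seen = set(map(str, labels)) | set(map(str, predictions))
    if not seen <= set(classes):
        raise ValueError(f"values outside the class set: {sorted(seen - set(classes))}")
    mcm = multilabel_confusion_matrix(labels, predictions, labels=list(classes))
    counts = {}
    for cls, m in zip(classes, mcm):
        tn, fp = int(m[0, 0]), int(m[0, 1])
        fn, tp = int(m[1, 0]), int(m[1, 1])
        counts[cls] = (tp, fn, fp, tn)
    return ConfusionTally(classes=classes, counts=counts)


def _metric_row(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    acc = ratio(tp + tn, tp + fn + fp + tn)
    sn = ratio(tp, tp + fn)
    sp = ratio(tn, fp + tn)
    pr = ratio(tp, tp + fp)
    if np.isnan(sn) or np.isnan(pr) or (pr + sn) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * pr * sn / (pr + sn)
    return {"Acc": acc, "Sn": sn, "Sp": sp, "Pr": pr, "F1": f1}


def metrics(tally_: ConfusionTally) -> pd.DataFrame:
    """Per-class metrics plus the macro "Average" row, as fractions.

    Undefined metrics (zero denominator) are NaN and are excluded from
    the average.
    """
    rows = {
        cls: _metric_row(*tally_.counts[cls]) for cls in tally_.classes
    }
    report = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRICS))
    report.loc["Average"] = macro_average(report)
    report.index.name = "class"
    return report


def macro_average(report: pd.DataFrame) -> pd.Series:
    """Unweighted mean over per-class rows, skipping undefined values."""
    per_class = report.loc[[i for i in report.index if i != "Average"]]
    with np.errstate(invalid="ignore"):
        return per_class.mean(axis=0, skipna=True)


def evaluate(labels, predictions, classes=None) -> pd.DataFrame:
    """Convenience: tally then metrics."""
    return metrics(tally(labels, predictions, classes))


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a metric report as CSV or JSON (by extension), 4 significant digits."""
    path = Path(path)
    rounded = report.map(lambda v: float(f"{v:.4g}") if np.isfinite(v) else None)
    if path.suffix == ".json":
        path.write_text(json.dumps(rounded.to_dict(orient="index"), indent=2))
    else:
        rounded.to_csv(path)
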