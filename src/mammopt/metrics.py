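"""Evaluation metrics for lesion segmentation and classification.

Two formula sets are exposed for the confusion-count metrics. ``"standard"``
(the default) uses the textbook definitions of FPR, NPV, specificity and F1.
``"as_printed"`` reproduces a variant formula set in which four of those
ratios deviate from the textbook forms (FPR with a TP-free denominator,
specificity normalised by FN+TP, an F1 that reduces to TP/(TP+FP+FN)).
Keeping both allows fidelity audits against reports that used the variant
forms while defaulting to the definitions the metric names imply.

Degenerate 0/0 cells are reported as ``Undefined`` sentinels rather than
NaN or exceptions so that batch reports stay machine readable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "Undefined",
    "UNDEFINED",
    "confusion_counts",
    "classification_metrics",
    "dice",
    "jaccard",
    "report_to_json",
    "reports_to_csv",
]

METRIC_COLUMNS = (
    "accuracy",
    "precision",
    "npv",
    "fdr",
    "specificity",
    "sensitivity",
    "f1",
    "fnr",
    "fpr",
    "mcc",
)


class Undefined(float):
    """Sentinel for a metric whose denominator was zero (0/0 cell).

    Compares equal to NaN semantics for arithmetic but is identifiable with
    ``isinstance`` and serialises as the string ``"undefined"``.
    """

    def __new__(cls, *args):
        # ignore args so copy/deepcopy (which replay float.__new__) work
        return float.__new__(cls, float("nan"))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "Undefined"


#: Shared sentinel instance.
UNDEFINED = Undefined()


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return UNDEFINED
    return num / den


@dataclass(frozen=True)
class ConfusionCounts:
    """The four binary-outcome tallies every confusion metric consumes.

    Attributes
    ----------
    tp, fp, tn, fn
        True-positive, false-positive, true-negative and false-negative
        counts. All non-negative integers; their sum is the number of
        evaluated items.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """All ten confusion-count metrics plus the formula mode that produced them."""

    accuracy: float
    precision: float
    npv: float
    fdr: float
    specificity: float
    sensitivity: float
    f1: float
    fnr: float
    fpr: float
    mcc: float
    mode: str = "standard"

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_counts(
    pred: Sequence, truth: Sequence, positive_label=1
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for a predicted vs true label sequence.

    Labels are compared against ``positive_label``; everything else is the
    negative class. Raises on empty input or length mismatch.
    """
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValueError(
            f"pred and truth must have equal length, got {len(pred)} vs {len(truth)}"
        )
    if not pred:
        raise ValueError("cannot tally an empty label sequence")
    p = np.asarray([x == positive_label for x in pred], dtype=bool)
    t = np.asarray([x == positive_label for x in truth], dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def classification_metrics(c: ConfusionCounts, mode: str = "standard") -> MetricReport:
    """Compute the ten-ratio report from confusion counts.

    ``mode="standard"`` uses textbook definitions throughout.
    ``mode="as_printed"`` swaps in the variant forms for FPR, NPV,
    specificity and F1 (see module docstring). Accuracy, precision,
    sensitivity, FDR, FNR and MCC are identical in both modes.
    """
    if mode not in ("standard", "as_printed"):
        raise ValueError(f"mode must be 'standard' or 'as_printed', got {mode!r}")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)

    accuracy = _ratio(tp + tn, tp + fp + tn + fn)
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    fdr = _ratio(fp, fp + tp)
    fnr = _ratio(fn, tp + fn)

    if mode == "as_printed":
        fpr = _ratio(fp, fn + fp)
        npv = _ratio(tn, fp + tn)
        specificity = _ratio(tn, fn + tp)
        f1 = _ratio(2.0 * tp, 2.0 * (tp + fp + fn))
    else:
        fpr = _ratio(fp, fp + tn)
        npv = _ratio(tn, tn + fn)
        specificity = _ratio(tn, tn + fp)
        f1 = _ratio(2.0 * tp, 2.0 * tp + fp + fn)

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = UNDEFINED if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den

    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        npv=npv,
        fdr=fdr,
        specificity=specificity,
        sensitivity=sensitivity,
        f1=f1,
        fnr=fnr,
        fpr=fpr,
        mcc=mcc,
        mode=mode,
    )


def _as_bool_mask(m) -> np.ndarray:
    a = np.asarray(m)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {a.shape}")
    uniq = np.unique(a)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask values must be strictly binary (0/1)")
    return a.astype(bool)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) between two binary masks.

    Both-empty masks score 1.0 (perfect agreement on absence).
    """
    aa, bb = _as_bool_mask(a), _as_bool_mask(b)
    if aa.shape != bb.shape:
        raise ValueError(f"mask shapes differ: {aa.shape} vs {bb.shape}")
    denom = int(aa.sum()) + int(bb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((aa & bb).sum()) / denom


def jaccard(a, b) -> float:
    """Jaccard overlap |A∩B|/|A∪B|; both-empty convention as for :func:`dice`."""
    aa, bb = _as_bool_mask(a), _as_bool_mask(b)
    if aa.shape != bb.shape:
        raise ValueError(f"mask shapes differ: {aa.shape} vs {bb.shape}")
    union = int((aa | bb).sum())
    if union == 0:
        return 1.0
    return int((aa & bb).sum()) / union


def _jsonable(v):
    if isinstance(v, Undefined) or (isinstance(v, float) and math.isnan(v)):
        return "undefined"
    return v


def report_to_json(report: MetricReport) -> str:
    """Serialise one report; undefined cells become the string "undefined"."""
    return json.dumps({k: _jsonable(v) for k, v in report.as_dict().items()})


def reports_to_csv(reports: Iterable[MetricReport], path) -> None:
    """Write reports as CSV, one row per report, fixed column order."""
    import pandas as pd

    rows = []
    for r in reports:
        d = r.as_dict()
        rows.append({k: _jsonable(d[k]) for k in (*METRIC_COLUMNS, "mode")})
    pd.DataFrame(rows, columns=[*METRIC_COLUMNS, "mode"]).to_csv(path, index=False)
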