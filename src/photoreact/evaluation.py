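"""Statistical evaluation of binary spectrum-class predictions.

Implements the four standard measures over confusion counts,

    SE  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    Q   = (TP + TN) / (TP + FN + TN + FP)
    MCC = (TP·TN − FN·FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

plus ROC curves with trapezoidal AUC and a model-comparison table sorted by
MCC then Q. POS is the positive class throughout. Display values are rounded
half-up to two decimals, matching reporting convention; full precision is
kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .labeling import NEG, POS


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    counts: ConfusionCounts
    se: float
    sp: float
    q: float
    mcc: float
    mcc_undefined: bool = False
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None
    oob_accuracy: float | None = None

    def rounded(self) -> dict[str, float]:
        """Two-decimal half-up display values."""
        return {k: round2(getattr(self, k)) for k in ("se", "sp", "q", "mcc")}


def round2(x: float) -> float:
    """Round half-up to 2 decimals (display convention; 0.875 -> 0.88)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def metrics_from_counts(c: ConfusionCounts) -> EvalReport:
    """SE, SP, Q and MCC from confusion counts.

    A zero marginal makes MCC undefined; it is then reported as 0 with the
    ``mcc_undefined`` flag set. SE/SP with an empty margin are NaN.
    """
    if c.total == 0:
        raise ValueError("no evaluated predictions")
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    q = (c.tp + c.tn) / c.total
    denom = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp)
    if denom == 0:
        mcc, undefined = 0.0, True
    else:
        mcc = (c.tp * c.tn - c.fn * c.fp) / math.sqrt(denom)
        undefined = False
    return EvalReport(c, se=se, sp=sp, q=q, mcc=mcc, mcc_undefined=undefined)


def confusion(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionCounts:
    """Tally confusion counts with POS as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == POS:
            tp += p == POS
            fn += p != POS
        else:
            tn += p != POS
            fp += p == POS
    return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def roc_points(
    y_true: Sequence[str], pos_scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve from POS-class scores: a threshold sweep over the distinct
    scores (ties grouped into one step) with trapezoidal AUC."""
    y = np.asarray([1 if t == POS else 0 for t in y_true])
    if len(set(y)) < 2:
        raise ValueError("ROC needs both classes in y_true")
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(pos_scores, dtype=float), drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    pos_scores: Sequence[float] | None = None,
    oob_accuracy: float | None = None,
) -> EvalReport:
    """Full report: counts, the four measures, and (given scores) ROC/AUC."""
    report = metrics_from_counts(confusion(y_true, y_pred))
    report.oob_accuracy = oob_accuracy
    if pos_scores is not None:
        report.roc, report.auc = roc_points(y_true, pos_scores)
    return report


def comparison_table(reports: Mapping[str, EvalReport]) -> pd.DataFrame:
    """Model-comparison table (rows sorted by descending MCC, then Q) in the
    column layout Q_tr / Q / SP / SE / MCC / TP / TN / FP / FN."""
    if not reports:
        raise ValueError("no reports to compare")
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "model": name,
                "q_tr": round2(r.oob_accuracy) if r.oob_accuracy is not None else math.nan,
                "q": round2(r.q),
                "sp": round2(r.sp),
                "se": round2(r.se),
                "mcc": round2(r.mcc),
                "tp": r.counts.tp,
                "tn": r.counts.tn,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "_mcc_full": r.mcc,
                "_q_full": r.q,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["_mcc_full", "_q_full"], ascending=False, kind="stable"
    )
    return df.drop(columns=["_mcc_full", "_q_full"]).reset_index(drop=True)
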