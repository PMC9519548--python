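"""Confusion counts and figures of merit for unbalanced two-class problems.

Beyond accuracy/sensitivity/specificity, the suite includes metrics robust to
class unbalance: precision, the F_beta score (beta = 2 by default, weighting
recall twice as much as precision — a false negative means a patient missed),
the Matthews correlation coefficient, Youden's index gamma, the positive and
negative likelihood ratios rho+/rho-, and the test effectiveness

    delta = (sqrt(3)/pi) * [ln(SENS/(1-SENS)) + ln(SPEC/(1-SPEC))],

the separation of the two class score means in pooled standard-deviation
units under a logistic model.  Boundary cases are handled exactly: a perfect
rate yields an infinite likelihood ratio / delta, represented as ``inf`` and
serialized as the string ``Inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN tallies with respect to a designated positive class."""

    TP: int
    FN: int
    FP: int
    TN: int
    positive_class: str = "AD"

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def confusion(true_labels, predicted_labels, positive_class: str = "AD") -> ConfusionCounts:
    """Tally a two-class confusion table (positive class defaults to AD)."""
    t = [str(v) for v in true_labels]
    p = [str(v) for v in predicted_labels]
    if len(t) != len(p):
        raise ValueError("label vectors must have equal length")
    if len(t) == 0:
        raise ValueError("empty label vectors")
    classes = set(t) | set(p)
    if positive_class not in classes and len(classes) > 1:
        raise ValueError(f"positive class {positive_class!r} not among labels {sorted(classes)}")
    if len(classes) > 2:
        raise ValueError(f"more than two labels present: {sorted(classes)}")
    if positive_class in ("AD", "HC") and not classes <= {"AD", "HC"}:
        raise ValueError(f"unknown label(s) {sorted(classes - {'AD', 'HC'})}")
    tp = sum(1 for a, b in zip(t, p) if a == positive_class and b == positive_class)
    fn = sum(1 for a, b in zip(t, p) if a == positive_class and b != positive_class)
    fp = sum(1 for a, b in zip(t, p) if a != positive_class and b == positive_class)
    tn = sum(1 for a, b in zip(t, p) if a != positive_class and b != positive_class)
    return ConfusionCounts(tp, fn, fp, tn, positive_class)


@dataclass
class FiguresOfMerit:
    """The full metric bundle; percentages on the 0-100 scale."""

    cc_positive: float      # per-class correct rate, positive class (%)
    cc_negative: float      # per-class correct rate, negative class (%)
    cc_overall: float       # 100 - (e1 + e2)/N * 100 == accuracy (%)
    accuracy: float         # %
    sensitivity: float      # %
    specificity: float      # %
    precision: float        # %
    f_beta: float           # %
    beta: float
    mcc: float
    youden: float           # gamma, %
    lr_pos: float           # rho+, may be inf
    lr_neg: float           # rho-
    delta: float            # test effectiveness, may be inf

    def to_dict(self) -> dict:
        return asdict(self)

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else 0.0
    return num / den


def rate_metrics(sens: float, spec: float) -> tuple[float, float, float, float]:
    """Youden's gamma, likelihood ratios rho+/rho-, and test effectiveness delta.

    All four are total on sens, spec in [0, 1]; boundary rates yield the
    documented infinities rather than errors.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sens and spec must be fractions in [0, 1]")
    youden = sens - (1.0 - spec)
    lr_pos = _safe_div(sens, 1.0 - spec)
    lr_neg = _safe_div(1.0 - sens, spec)

    def logit(p: float) -> float:
        if p <= 0.0:
            return -math.inf
        if p >= 1.0:
            return math.inf
        return math.log(p / (1.0 - p))

    delta = (math.sqrt(3.0) / math.pi) * (logit(sens) + logit(spec))
    return youden, lr_pos, lr_neg, delta


def figures_of_merit(counts: ConfusionCounts, beta: float = 2.0) -> FiguresOfMerit:
    """Compute the full figure-of-merit suite from confusion counts.

    Percentages are kept at full precision internally; report writers round
    to 2 decimals.  ``beta`` weights recall against precision in F_beta.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    if beta <= 0:
        raise ValueError("beta must be positive")
    TP, FN, FP, TN = counts.TP, counts.FN, counts.FP, counts.TN
    n_pos, n_neg = TP + FN, TN + FP

    accuracy = 100.0 * (TP + TN) / counts.total
    sens = _safe_div(TP, n_pos)
    spec = _safe_div(TN, n_neg)
    # per-class correct rates (CC%) and the overall rate with errors summed
    cc_pos = 100.0 * sens if n_pos else math.nan
    cc_neg = 100.0 * spec if n_neg else math.nan
    cc_overall = 100.0 - 100.0 * (FN + FP) / counts.total

    precision = 100.0 * _safe_div(TP, TP + FP) if (TP + FP) else 0.0
    if precision == 0.0 and 100.0 * sens == 0.0:
        f_beta = 0.0
    else:
        f_beta = (1.0 + beta**2) * (precision * 100.0 * sens) / (beta**2 * precision + 100.0 * sens)

    mcc_den = math.sqrt((TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    mcc = (TP * TN - FP * FN) / mcc_den if mcc_den > 0 else 0.0

    youden, lr_pos, lr_neg, delta = rate_metrics(min(sens, 1.0), min(spec, 1.0))
    return FiguresOfMerit(
        cc_positive=cc_pos, cc_negative=cc_neg, cc_overall=cc_overall,
        accuracy=accuracy, sensitivity=100.0 * sens, specificity=100.0 * spec,
        precision=precision, f_beta=f_beta, beta=beta, mcc=mcc,
        youden=100.0 * youden, lr_pos=lr_pos, lr_neg=lr_neg, delta=delta,
    )


def _fmt(v: float, nd: int = 2) -> str:
    if math.isinf(v):
        return "Inf"
    return f"{v:.{nd}f}"


def merit_table(per_model: dict[str, FiguresOfMerit]) -> pd.DataFrame:
    """Figures-of-merit report, metric rows x model columns (2 dp, Inf literal)."""
    rows = [
        ("Accuracy (%)", "accuracy", 2), ("Sensitivity (%)", "sensitivity", 2),
        ("Specificity (%)", "specificity", 2), ("Precision (%)", "precision", 2),
        ("F_beta-score (%)", "f_beta", 2), ("MCC", "mcc", 2),
        ("gamma (%)", "youden", 2), ("rho+", "lr_pos", 2),
        ("rho-", "lr_neg", 3), ("delta", "delta", 2),
    ]
    data = {
        model: [_fmt(getattr(fom, attr), nd) for _, attr, nd in rows]
        for model, fom in per_model.items()
    }
    return pd.DataFrame(data, index=[name for name, _, _ in rows])


def cc_table(per_stage: dict[str, ConfusionCounts], positive_class: str = "AD") -> pd.DataFrame:
    """Per-stage, per-class correct classification rates (%), 2 dp."""
    rows = {}
    for stage, counts in per_stage.items():
        fom = figures_of_merit(counts)
        rows[stage] = {
            positive_class: round(fom.cc_positive, 2),
            "other": round(fom.cc_negative, 2),
        }
    return pd.DataFrame(rows).T
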