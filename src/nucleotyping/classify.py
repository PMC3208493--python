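"""Single-feature linear discriminant classification and its evaluation.

A two-class linear discriminant on one feature with a pooled variance
reduces to a threshold: with equal priors the decision boundary sits at the
midpoint of the class means (the pooled variance cancels), and with unequal
priors it shifts by ``s2 * ln(prior_neg / prior_pos) / (m_pos - m_neg)``.
The feature (of f_plus, f_minus, f_diff) with the highest training-set
correct classification rate (CCR) is selected and then applied unchanged to
the held-out test set.

Evaluation follows the usual 2x2 contingency machinery: sensitivity,
specificity, CCR and the Pearson chi-squared statistic without continuity
correction,

    chi2 = n * (tn*tp - fp*fn)**2 / ((tn+fp)(fn+tp)(tn+fn)(fp+tp)).

The nucleotyping and DNA-ploidy calls combine into a panel score by an OR
rule: a patient is combined-positive when either marker is positive, and a
missing ploidy result counts as ploidy-negative so the patient is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("f_plus", "f_minus", "f_diff")


@dataclass(frozen=True)
class LinearThreshold:
    """Fitted 1-D linear discriminant: a cut point plus its orientation."""

    threshold: float
    positive_above: bool

    def predict(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=np.float64)
        return x > self.threshold if self.positive_above else x < self.threshold


def fit_lda_1d(
    values,
    is_positive,
    priors: tuple[float, float] | None = None,
) -> LinearThreshold:
    """Fit the threshold of a two-class 1-D linear discriminant.

    ``priors`` are (positive, negative) class priors; equal by default, in
    which case the threshold is exactly the midpoint of the class means.
    With zero pooled variance the midpoint is used regardless of priors.
    Identical class means are non-separable and raise.
    """
    x = np.asarray(values, dtype=np.float64)
    y = np.asarray(is_positive, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to fit a discriminant")
    m_pos, m_neg = x[y].mean(), x[~y].mean()
    if m_pos == m_neg:
        raise ValueError("identical class means: feature is non-separable")
    t = 0.5 * (m_pos + m_neg)
    if priors is not None:
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        ss = ((x[y] - m_pos) ** 2).sum() + ((x[~y] - m_neg) ** 2).sum()
        dof = max(n_pos + n_neg - 2, 1)
        s2 = ss / dof
        if s2 > 0:
            t += s2 * np.log(priors[1] / priors[0]) / (m_pos - m_neg)
    return LinearThreshold(threshold=float(t), positive_above=bool(m_pos > m_neg))


def ccr(rule: LinearThreshold, values, is_positive) -> float:
    """Correct classification rate of a fitted rule, as a fraction."""
    pred = rule.predict(values)
    return float(np.mean(pred == np.asarray(is_positive, dtype=bool)))


@dataclass
class SelectedFeature:
    name: str
    rule: LinearThreshold
    train_ccr: float
    ccr_by_feature: dict[str, float]


def select_feature(
    features: pd.DataFrame,
    is_positive,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    priors: tuple[float, float] | None = None,
) -> SelectedFeature:
    """Fit a discriminant per candidate feature and keep the training-CCR
    argmax.  Exact ties go to the earliest feature in ``feature_names``
    (f_plus before f_minus before f_diff) and are logged."""
    y = np.asarray(is_positive, dtype=bool)
    rules: dict[str, LinearThreshold] = {}
    ccrs: dict[str, float] = {}
    for name in feature_names:
        rules[name] = fit_lda_1d(features[name].to_numpy(), y, priors=priors)
        ccrs[name] = ccr(rules[name], features[name].to_numpy(), y)
    best = max(ccrs.values())
    winners = [n for n in feature_names if ccrs[n] == best]
    if len(winners) > 1:
        logger.info(
            "training CCR tie between %s at %.3f; selecting %s",
            winners, best, winners[0],
        )
    name = winners[0]
    return SelectedFeature(
        name=name, rule=rules[name], train_ccr=best, ccr_by_feature=ccrs
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts of a 2x2 test-vs-truth table.

    Rows are the true classes (negative = no dysplasia, positive = HGD);
    ``positive`` means test-positive (NT-positive, ploidy-abnormal, or
    combined-positive).
    """

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_calls(cls, truth, calls) -> "ConfusionMatrix2x2":
        t = np.asarray(truth, dtype=bool)
        c = np.asarray(calls, dtype=bool)
        return cls(
            tn=int((~t & ~c).sum()),
            fp=int((~t & c).sum()),
            fn=int((t & ~c).sum()),
            tp=int((t & c).sum()),
        )


@dataclass
class EvalReport:
    """Sensitivity/specificity/CCR in percent plus Pearson chi-squared."""

    sensitivity: float
    specificity: float
    ccr: float
    pearson_chi2: float | None
    n: int
    chi2_note: str = ""

    @property
    def sensitivity_pct(self) -> int:
        return round(self.sensitivity)

    @property
    def specificity_pct(self) -> int:
        return round(self.specificity)

    @property
    def ccr_pct(self) -> int:
        return round(self.ccr)


def evaluate(cm: ConfusionMatrix2x2) -> EvalReport:
    """Summary statistics of a 2x2 confusion matrix.

    The chi-squared statistic carries no continuity correction; it is
    reported as absent (None, with a note) when any marginal is zero.
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else float("nan")
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else float("nan")
    rate = 100.0 * (cm.tp + cm.tn) / n
    marginals = (cm.tn + cm.fp, cm.fn + cm.tp, cm.tn + cm.fn, cm.fp + cm.tp)
    if 0 in marginals:
        chi2, note = None, "chi-squared undefined: zero marginal total"
    else:
        num = n * (cm.tn * cm.tp - cm.fp * cm.fn) ** 2
        chi2, note = num / np.prod(marginals, dtype=np.float64), ""
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        ccr=rate,
        pearson_chi2=None if chi2 is None else float(chi2),
        n=n,
        chi2_note=note,
    )


def combine_nt_icm(
    nt_calls: Mapping[str, bool], icm_calls: Mapping[str, bool | None]
) -> dict[str, bool]:
    """Panel score: positive when NT or ICM is positive.

    A missing ICM call counts as ICM-negative (the patient is retained);
    a patient without an NT call is excluded with a warning.
    """
    out: dict[str, bool] = {}
    for pid in set(nt_calls) | set(icm_calls):
        nt = nt_calls.get(pid)
        if nt is None:
            warnings.warn(
                f"patient {pid!r}: no nucleotyping call; excluded from the "
                "combined score",
                stacklevel=2,
            )
            continue
        icm = icm_calls.get(pid)
        out[pid] = bool(nt) or bool(icm)
    return out


def report_row(name: str, cm: ConfusionMatrix2x2, rep: EvalReport) -> dict:
    return {
        "method": name,
        "tn": cm.tn,
        "fp": cm.fp,
        "fn": cm.fn,
        "tp": cm.tp,
        "n": rep.n,
        "sensitivity": rep.sensitivity,
        "specificity": rep.specificity,
        "ccr": rep.ccr,
        "pearson_chi2": rep.pearson_chi2,
    }


def format_confusion_table(
    reports: dict[str, tuple[ConfusionMatrix2x2, EvalReport]]
) -> str:
    """Human-readable confusion-matrix panel (rows: no dysplasia / HGD;
    columns: call 0 / 1 / total) for each method."""
    lines = []
    for name, (cm, rep) in reports.items():
        chi2 = "n/a" if rep.pearson_chi2 is None else f"{rep.pearson_chi2:.1f}"
        lines.append(f"{name} - Pearson chi2 = {chi2}")
        lines.append(f"{'':<14}{'0':>6}{'1':>6}{'Total':>8}")
        lines.append(f"{'No dysplasia':<14}{cm.tn:>6}{cm.fp:>6}{cm.tn + cm.fp:>8}")
        lines.append(f"{'HGD':<14}{cm.fn:>6}{cm.tp:>6}{cm.fn + cm.tp:>8}")
        lines.append(
            f"{'Total':<14}{cm.tn + cm.fn:>6}{cm.fp + cm.tp:>6}{cm.n:>8}"
        )
        lines.append(
            f"sensitivity {rep.sensitivity_pct}%  specificity "
            f"{rep.specificity_pct}%  CCR {rep.ccr_pct}%"
        )
        lines.append("")
    return "\n".join(lines)
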