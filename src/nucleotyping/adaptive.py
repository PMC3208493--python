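"""Adaptive Mahalanobis-weighted GLEM texture features.

Instead of fixed weight functions over the GLEM, the adaptive approach learns
its weights from training data.  Within each nuclear area interval A_a the
training set provides, for each class, an element-wise mean matrix
``Pbar(i,j | w, A_a, class)`` and variance matrix ``var(i,j | ...)`` computed
in two steps — first within each case, then averaged (unweighted) across the
cases of a class — so a case with many nuclei cannot bias the class
statistics.  From these, per area group:

* class difference matrix  ``delta = Pbar_dysplastic - Pbar_nondysplastic``
* squared elemental Mahalanobis distance
  ``d2 = delta**2 / ((var_1 + var_2) / 2 + eps)``

Each nucleus then yields two features by a weighted summation of its GLEM
with weights ``d2``, split over the sign partition of ``delta``::

    f_plus  = sum over elements with delta > 0 of d2 * P
    f_minus = sum over elements with delta < 0 of d2 * P

Patient-level values are unweighted means over the patient's nuclei in area
groups A1-A5; ``f_diff = f_plus - f_minus`` completes the three candidate
features handed to the classifier.  The dysplastic class is fixed as class 1,
so the sign convention of ``delta`` (and hence which partition feeds
``f_plus``) is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gallery import LABELS
from .glem import Glem

CLASS_ORDER = ("dysplastic", "nondysplastic")  # class 1, class 2
FEATURE_AREA_GROUPS = (1, 2, 3, 4, 5)
DEFAULT_EPSILON = 1e-8


@dataclass
class NucleusGlem:
    """One nucleus's GLEM with the grouping keys the fit needs."""

    patient_id: str
    label: str
    area_group: int
    P: np.ndarray


def glem_record(
    glem: Glem, patient_id: str, label: str, area_group_index: int
) -> NucleusGlem:
    return NucleusGlem(
        patient_id=patient_id, label=label, area_group=area_group_index, P=glem.P
    )


@dataclass
class ClassStats:
    """Per (area group, class) statistics averaged over training cases."""

    mean: np.ndarray
    var: np.ndarray
    n_cases: int


@dataclass
class ClassStatMatrices:
    """Mapping ``(area_group, label) -> ClassStats`` fitted on training data."""

    stats: dict[tuple[int, str], ClassStats] = field(default_factory=dict)

    def area_groups(self) -> list[int]:
        return sorted({a for a, _ in self.stats})

    def both_classes(self, area_group: int) -> bool:
        return all((area_group, lab) in self.stats for lab in CLASS_ORDER)


def fit_class_statistics(
    records: list[NucleusGlem],
    area_groups: tuple[int, ...] = FEATURE_AREA_GROUPS,
) -> ClassStatMatrices:
    """Two-step class statistics: per-case mean/variance of the nuclear
    GLEMs, then an unweighted average of the per-case matrices across the
    cases of each class.

    Per-case variances use the population (divide-by-n) formula; a case with
    a single nucleus in a group contributes zero variance there.
    """
    for rec in records:
        if rec.label not in LABELS:
            raise ValueError(f"unknown class label {rec.label!r}")
    for label in CLASS_ORDER:
        cases = {r.patient_id for r in records if r.label == label}
        if not cases:
            raise ValueError(f"no training cases for class {label!r}")
        if len(cases) < 2:
            warnings.warn(
                f"class {label!r} has a single training case; class variance "
                "across cases is not estimable",
                stacklevel=2,
            )

    by_case_group: dict[tuple[str, int], list[np.ndarray]] = {}
    case_label: dict[str, str] = {}
    for rec in records:
        if rec.area_group not in area_groups:
            continue
        by_case_group.setdefault((rec.patient_id, rec.area_group), []).append(rec.P)
        case_label[rec.patient_id] = rec.label

    # step 1: within-case mean and population variance per area group
    case_stats: dict[tuple[int, str], list[tuple[np.ndarray, np.ndarray]]] = {}
    for (pid, a), mats in by_case_group.items():
        stack = np.stack(mats)
        case_stats.setdefault((a, case_label[pid]), []).append(
            (stack.mean(axis=0), stack.var(axis=0))
        )

    # step 2: unweighted average of the per-case matrices across cases
    out = ClassStatMatrices()
    for (a, label), pairs in case_stats.items():
        means = np.stack([m for m, _ in pairs])
        varis = np.stack([v for _, v in pairs])
        out.stats[(a, label)] = ClassStats(
            mean=means.mean(axis=0), var=varis.mean(axis=0), n_cases=len(pairs)
        )
    return out


@dataclass
class AreaDiscriminant:
    """Difference and squared-Mahalanobis weight matrices for one area group."""

    delta: np.ndarray
    d2: np.ndarray


@dataclass
class DiscriminantMatrices:
    """Mapping ``area_group -> AreaDiscriminant``."""

    by_group: dict[int, AreaDiscriminant] = field(default_factory=dict)
    epsilon: float = DEFAULT_EPSILON

    def area_groups(self) -> list[int]:
        return sorted(self.by_group)


def derive_discriminants(
    stats: ClassStatMatrices, epsilon: float = DEFAULT_EPSILON
) -> DiscriminantMatrices:
    """Element-wise class difference and squared Mahalanobis distance.

    ``d2 = delta**2 / ((var_1 + var_2)/2 + epsilon)``; the regulariser keeps
    rare matrix elements (both variances zero) finite: there
    ``d2 = delta**2 / epsilon``, and elements with ``delta = 0`` get 0.
    Area groups lacking either class are omitted.
    """
    out = DiscriminantMatrices(epsilon=epsilon)
    for a in stats.area_groups():
        if not stats.both_classes(a):
            continue
        s1 = stats.stats[(a, CLASS_ORDER[0])]
        s2 = stats.stats[(a, CLASS_ORDER[1])]
        delta = s1.mean - s2.mean
        d2 = delta**2 / (0.5 * (s1.var + s2.var) + epsilon)
        out.by_group[a] = AreaDiscriminant(delta=delta, d2=d2)
    return out


def nucleus_features(
    P: np.ndarray | Glem, disc: AreaDiscriminant
) -> tuple[float, float]:
    """Weighted GLEM sums over the positive / negative partition of delta."""
    if isinstance(P, Glem):
        P = P.P
    f_plus = float((disc.d2 * P)[disc.delta > 0].sum())
    f_minus = float((disc.d2 * P)[disc.delta < 0].sum())
    return f_plus, f_minus


@dataclass
class PatientFeatures:
    patient_id: str
    f_plus: float
    f_minus: float
    f_diff: float
    n_nuclei_used: int


def patient_features(
    records: list[NucleusGlem],
    discriminants: DiscriminantMatrices,
    feature_area_groups: tuple[int, ...] = FEATURE_AREA_GROUPS,
) -> PatientFeatures | None:
    """Unweighted mean nucleus features of one patient over area groups A1-A5.

    Nuclei outside the feature area groups, or in groups with no fitted
    discriminant, are excluded.  Returns None (with a warning) when no
    eligible nucleus remains — the patient is unscorable.
    """
    if not records:
        return None
    pid = records[0].patient_id
    fp, fm = [], []
    for rec in records:
        if rec.area_group not in feature_area_groups:
            continue
        disc = discriminants.by_group.get(rec.area_group)
        if disc is None:
            continue
        a, b = nucleus_features(rec.P, disc)
        fp.append(a)
        fm.append(b)
    if not fp:
        warnings.warn(
            f"patient {pid!r}: no nucleus in area groups "
            f"{feature_area_groups} with a fitted discriminant; unscorable",
            stacklevel=2,
        )
        return None
    f_plus = float(np.mean(fp))
    f_minus = float(np.mean(fm))
    return PatientFeatures(
        patient_id=pid,
        f_plus=f_plus,
        f_minus=f_minus,
        f_diff=f_plus - f_minus,
        n_nuclei_used=len(fp),
    )


def feature_table(
    records: list[NucleusGlem],
    discriminants: DiscriminantMatrices,
    feature_area_groups: tuple[int, ...] = FEATURE_AREA_GROUPS,
) -> pd.DataFrame:
    """Per-patient feature table (patient_id, f_plus, f_minus, f_diff,
    n_nuclei_used) over all patients present in ``records``; unscorable
    patients are dropped with a warning."""
    by_patient: dict[str, list[NucleusGlem]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    rows = []
    for pid in sorted(by_patient):
        pf = patient_features(by_patient[pid], discriminants, feature_area_groups)
        if pf is not None:
            rows.append(vars(pf))
    return pd.DataFrame(
        rows, columns=["patient_id", "f_plus", "f_minus", "f_diff", "n_nuclei_used"]
    )
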