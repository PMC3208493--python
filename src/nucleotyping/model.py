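"""Patient-level nucleotyping model, results and the full study pipeline.

The public surface follows the fit/results convention of statistical
modelling packages::

    model = NucleotypingModel.from_cohort(cohort)
    res = model.fit()
    print(res.summary())
    res.save("classifier.npz")

``NucleotypingModel`` holds per-nucleus GLEMs plus the case table;
``fit`` learns the per-area-group class statistics and Mahalanobis weight
matrices on the training cases, extracts the per-patient adaptive features
(f_plus, f_minus, f_diff), selects the single feature with the highest
training CCR under a 1-D linear discriminant, and applies it to every
patient.  The returned ``NucleotypingResults`` carries the feature table,
the fitted ``NucleotypingClassifier`` (serialisable), and train/test/all
evaluation reports.  ``run_study`` additionally runs the DNA-ploidy arm and
the combined NT-or-ICM panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adaptive, classify, ploidy as ploidy_mod
from .adaptive import (
    DiscriminantMatrices,
    FEATURE_AREA_GROUPS,
    NucleusGlem,
    AreaDiscriminant,
)
from .gallery import Cohort, NucleusImage, area_group, requantise, validate_case_table
from .glem import GlemParams, compute_glem

MODEL_SCHEMA_VERSION = 1


def glem_records_from_cohort(
    cohort: Cohort, params: GlemParams | None = None
) -> list[NucleusGlem]:
    """Re-quantise every nucleus and compute its GLEM and area group."""
    params = params or GlemParams()
    grey_depth = int(cohort.meta.get("grey_depth", 1024))
    labels = dict(zip(cohort.cases["patient_id"], cohort.cases["label"]))
    records = []
    for pid, nuclei in cohort.patients.items():
        for nuc in nuclei:
            rq = requantise(nuc, grey_depth, params.grey_levels)
            records.append(
                NucleusGlem(
                    patient_id=pid,
                    label=labels[pid],
                    area_group=area_group(nuc.area),
                    P=compute_glem(rq, params).P,
                )
            )
    return records


@dataclass
class NucleotypingClassifier:
    """A fitted, serialisable nucleotyping classifier.

    Holds everything needed to score new galleries: the GLEM parameters, the
    per-area-group difference/weight matrices, and the selected feature with
    its threshold rule.
    """

    glem_params: GlemParams
    discriminants: DiscriminantMatrices
    selected_feature: str
    rule: classify.LinearThreshold
    feature_area_groups: tuple[int, ...] = FEATURE_AREA_GROUPS

    def score_patients(self, records: list[NucleusGlem]) -> pd.DataFrame:
        """Per-patient features and NT calls for arbitrary GLEM records."""
        feats = adaptive.feature_table(
            records, self.discriminants, self.feature_area_groups
        )
        feats["nt_call"] = self.rule.predict(feats[self.selected_feature].to_numpy())
        return feats

    def save(self, path) -> None:
        header = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "glem_params": {
                "window": self.glem_params.window,
                "grey_levels": self.glem_params.grey_levels,
                "entropy_bins": self.glem_params.entropy_bins,
                "entropy_max": self.glem_params.entropy_max,
            },
            "epsilon": self.discriminants.epsilon,
            "selected_feature": self.selected_feature,
            "threshold": self.rule.threshold,
            "positive_above": self.rule.positive_above,
            "feature_area_groups": list(self.feature_area_groups),
            "area_groups": self.discriminants.area_groups(),
            "class_order": list(adaptive.CLASS_ORDER),
        }
        arrays = {"header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
        for a, disc in self.discriminants.by_group.items():
            arrays[f"delta_{a}"] = disc.delta
            arrays[f"d2_{a}"] = disc.d2
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "NucleotypingClassifier":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"].tobytes()).decode())
            if header["schema_version"] != MODEL_SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported classifier schema version "
                    f"{header['schema_version']}"
                )
            discs = DiscriminantMatrices(epsilon=header["epsilon"])
            for a in header["area_groups"]:
                discs.by_group[a] = AreaDiscriminant(
                    delta=data[f"delta_{a}"], d2=data[f"d2_{a}"]
                )
        return cls(
            glem_params=GlemParams(**header["glem_params"]),
            discriminants=discs,
            selected_feature=header["selected_feature"],
            rule=classify.LinearThreshold(
                threshold=header["threshold"],
                positive_above=header["positive_above"],
            ),
            feature_area_groups=tuple(header["feature_area_groups"]),
        )


class NucleotypingModel:
    """Adaptive-texture nucleotyping classifier for a two-class cohort.

    Parameters
    ----------
    records : list of NucleusGlem
        Per-nucleus GLEMs with patient id, class label and area group.
    cases : DataFrame
        Case table with columns patient_id, label, split.
    glem_params : GlemParams
        Texture-matrix parameters the records were computed with.
    epsilon : float
        Regulariser of the Mahalanobis denominator.
    priors : tuple or None
        (dysplastic, nondysplastic) priors of the discriminant; equal when
        None.
    """

    def __init__(
        self,
        records: list[NucleusGlem],
        cases: pd.DataFrame,
        glem_params: GlemParams | None = None,
        epsilon: float = adaptive.DEFAULT_EPSILON,
        feature_area_groups: tuple[int, ...] = FEATURE_AREA_GROUPS,
        priors: tuple[float, float] | None = None,
    ):
        self.records = records
        self.cases = validate_case_table(cases).reset_index(drop=True)
        self.glem_params = glem_params or GlemParams()
        self.epsilon = epsilon
        self.feature_area_groups = feature_area_groups
        self.priors = priors

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, glem_params: GlemParams | None = None, **kwargs
    ) -> "NucleotypingModel":
        glem_params = glem_params or GlemParams()
        records = glem_records_from_cohort(cohort, glem_params)
        return cls(records, cohort.cases, glem_params=glem_params, **kwargs)

    def fit(self) -> "NucleotypingResults":
        cases = self.cases
        if not {"train", "test"} <= set(cases["split"]):
            raise ValueError("case table must contain both train and test cases")
        train_ids = set(cases.loc[cases["split"] == "train", "patient_id"])
        train_records = [r for r in self.records if r.patient_id in train_ids]
        stats = adaptive.fit_class_statistics(train_records, self.feature_area_groups)
        discs = adaptive.derive_discriminants(stats, self.epsilon)

        feats = adaptive.feature_table(self.records, discs, self.feature_area_groups)
        feats = feats.merge(cases, on="patient_id", how="inner")
        feats["is_dysplastic"] = feats["label"] == "dysplastic"

        train = feats[feats["split"] == "train"]
        selected = classify.select_feature(
            train, train["is_dysplastic"].to_numpy(), priors=self.priors
        )
        feats["nt_call"] = selected.rule.predict(
            feats[selected.name].to_numpy()
        )

        clf = NucleotypingClassifier(
            glem_params=self.glem_params,
            discriminants=discs,
            selected_feature=selected.name,
            rule=selected.rule,
            feature_area_groups=self.feature_area_groups,
        )
        return NucleotypingResults(
            model=self,
            classifier=clf,
            class_stats=stats,
            features=feats,
            selected=selected,
        )


@dataclass
class NucleotypingResults:
    """Fitted nucleotyping classifier plus its per-patient scores."""

    model: NucleotypingModel
    classifier: NucleotypingClassifier
    class_stats: adaptive.ClassStatMatrices
    features: pd.DataFrame
    selected: classify.SelectedFeature

    @property
    def selected_feature(self) -> str:
        return self.selected.name

    @property
    def rule(self) -> classify.LinearThreshold:
        return self.selected.rule

    def confusion(self, split: str | None = None) -> classify.ConfusionMatrix2x2:
        df = self.features if split is None else self.features[
            self.features["split"] == split
        ]
        return classify.ConfusionMatrix2x2.from_calls(
            df["is_dysplastic"].to_numpy(), df["nt_call"].to_numpy()
        )

    def report(self, split: str | None = None) -> classify.EvalReport:
        return classify.evaluate(self.confusion(split))

    def nt_calls(self) -> dict[str, bool]:
        return dict(
            zip(self.features["patient_id"], self.features["nt_call"].astype(bool))
        )

    def save(self, path) -> None:
        self.classifier.save(path)

    def summary(self) -> str:
        train, test = self.report("train"), self.report("test")
        overall = self.report()
        lines = [
            "          Nucleotyping Classification Results",
            "=" * 56,
            f"Selected feature:     {self.selected_feature}",
            f"Threshold:            {self.rule.threshold:.6g} "
            f"({'positive above' if self.rule.positive_above else 'positive below'})",
            "Training CCR by feature: "
            + "  ".join(
                f"{k}={100 * v:.1f}%" for k, v in self.selected.ccr_by_feature.items()
            ),
            f"Train CCR:            {train.ccr:.1f}%  (n={train.n})",
            f"Test CCR:             {test.ccr:.1f}%  (n={test.n})",
            f"All cases:            CCR {overall.ccr:.1f}%, "
            f"sensitivity {overall.sensitivity_pct}%, "
            f"specificity {overall.specificity_pct}%  (n={overall.n})",
            "=" * 56,
        ]
        return "\n".join(lines)

    def plot_features(self, ax=None):
        """Per-class distribution of the selected feature with the threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, color in (("nondysplastic", "tab:blue"), ("dysplastic", "tab:red")):
            vals = self.features.loc[
                self.features["label"] == label, self.selected_feature
            ]
            ax.hist(vals, bins=15, alpha=0.6, color=color, label=label)
        ax.axvline(self.rule.threshold, color="k", linestyle="--", label="threshold")
        ax.set_xlabel(self.selected_feature)
        ax.set_ylabel("patients")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# full study: texture arm + ploidy arm + combined panel


@dataclass
class StudyReport:
    """End-to-end study output: NT results, ploidy table, panel reports."""

    results: NucleotypingResults
    ploidy_results: list[ploidy_mod.PloidyResult]
    reports: dict[str, tuple[classify.ConfusionMatrix2x2, classify.EvalReport]] = field(
        default_factory=dict
    )

    def ploidy_table(self) -> pd.DataFrame:
        return ploidy_mod.ploidy_table(self.ploidy_results)

    def summary(self) -> str:
        return (
            self.results.summary()
            + "\n\n"
            + classify.format_confusion_table(self.reports)
        )


def run_study(
    cohort: Cohort,
    glem_params: GlemParams | None = None,
    rules: ploidy_mod.PloidyRules | None = None,
    epsilon: float = adaptive.DEFAULT_EPSILON,
    priors: tuple[float, float] | None = None,
) -> StudyReport:
    """Run the whole pipeline on a cohort: NT classifier, per-patient DNA
    ploidy, and the combined NT-or-ICM panel evaluated over all cases."""
    model = NucleotypingModel.from_cohort(
        cohort, glem_params=glem_params, epsilon=epsilon, priors=priors
    )
    res = model.fit()

    background = float(cohort.meta.get("background_intensity", 800))
    ploidy_results = []
    for pid in cohort.cases["patient_id"]:
        iods = ploidy_mod.gallery_iods(cohort.patients[pid], background)
        ploidy_results.append(
            ploidy_mod.ploidy_summary(iods, rules=rules, patient_id=pid)
        )

    truth = dict(
        zip(cohort.cases["patient_id"], cohort.cases["label"] == "dysplastic")
    )
    nt_calls = res.nt_calls()
    icm_calls = {r.patient_id: r.is_abnormal for r in ploidy_results}
    combined = classify.combine_nt_icm(nt_calls, icm_calls)

    reports = {}
    for name, calls in (
        ("Nucleotyping", nt_calls),
        ("ICM", icm_calls),
        ("Combined score", combined),
    ):
        pids = sorted(calls)
        cm = classify.ConfusionMatrix2x2.from_calls(
            [truth[p] for p in pids], [calls[p] for p in pids]
        )
        reports[name] = (cm, classify.evaluate(cm))
    return StudyReport(results=res, ploidy_results=ploidy_results, reports=reports)
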