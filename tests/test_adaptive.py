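"""Adaptive Mahalanobis-weighted features: two-step statistics, weight
matrices, nucleus and patient feature extraction."""

import numpy as np
import pytest

from nucleotyping.adaptive import (
    AreaDiscriminant,
    DiscriminantMatrices,
    NucleusGlem,
    derive_discriminants,
    feature_table,
    fit_class_statistics,
    nucleus_features,
    patient_features,
)


def _records(case_mats, area_group=1):
    """case_mats: dict patient -> (label, list of matrices)."""
    out = []
    for pid, (label, mats) in case_mats.items():
        for P in mats:
            out.append(
                NucleusGlem(patient_id=pid, label=label, area_group=area_group, P=np.asarray(P))
            )
    return out


def nested_loop_stats(case_mats):
    """Independent mean-of-means / mean-of-variances oracle (pure python)."""
    per_case = {}
    for pid, (label, mats) in case_mats.items():
        arr = np.array(mats, dtype=float)
        n = len(mats)
        mean = sum(m for m in arr) / n
        var = sum((m - mean) ** 2 for m in arr) / n
        per_case.setdefault(label, []).append((mean, var))
    out = {}
    for label, pairs in per_case.items():
        out[label] = (
            sum(m for m, _ in pairs) / len(pairs),
            sum(v for _, v in pairs) / len(pairs),
        )
    return out


class TestFitClassStatistics:
    def test_matches_nested_loop_oracle(self, rng):
        case_mats = {}
        labels = ["dysplastic", "dysplastic", "nondysplastic", "nondysplastic", "dysplastic", "nondysplastic"]
        for k, label in enumerate(labels):
            case_mats[f"p{k}"] = (label, [rng.random((3, 3)) for _ in range(5)])
        stats = fit_class_statistics(_records(case_mats), area_groups=(1,))
        want = nested_loop_stats(case_mats)
        for label in ("dysplastic", "nondysplastic"):
            got = stats.stats[(1, label)]
            np.testing.assert_allclose(got.mean, want[label][0], atol=1e-12)
            np.testing.assert_allclose(got.var, want[label][1], atol=1e-12)
            assert got.n_cases == 3

    def test_cases_weighted_equally_regardless_of_nucleus_count(self, rng):
        big = [np.full((2, 2), 1.0)] * 50
        small = [np.full((2, 2), 0.0)] * 2
        case_mats = {
            "a": ("dysplastic", big),
            "b": ("dysplastic", small),
            "c": ("nondysplastic", [rng.random((2, 2))] * 3),
            "d": ("nondysplastic", [rng.random((2, 2))] * 3),
        }
        stats = fit_class_statistics(_records(case_mats), area_groups=(1,))
        # mean of per-case means = 0.5; pooled-nucleus mean would be 50/52
        np.testing.assert_allclose(stats.stats[(1, "dysplastic")].mean, 0.5)

    def test_identical_glems_give_zero_variance_and_zero_delta(self):
        P = np.full((2, 2), 0.25)
        case_mats = {
            "a": ("dysplastic", [P, P]),
            "b": ("dysplastic", [P]),
            "c": ("nondysplastic", [P, P]),
            "d": ("nondysplastic", [P]),
        }
        stats = fit_class_statistics(_records(case_mats), area_groups=(1,))
        discs = derive_discriminants(stats)
        np.testing.assert_array_equal(discs.by_group[1].delta, 0.0)
        np.testing.assert_array_equal(discs.by_group[1].d2, 0.0)
        for key in stats.stats:
            np.testing.assert_array_equal(stats.stats[key].var, 0.0)

    def test_missing_class_rejected(self):
        case_mats = {"a": ("dysplastic", [np.eye(2)]), "b": ("dysplastic", [np.eye(2)])}
        with pytest.raises(ValueError, match="nondysplastic"):
            fit_class_statistics(_records(case_mats), area_groups=(1,))


class TestDeriveDiscriminants:
    def test_stated_formula(self):
        stats = fit_class_statistics(
            _records(
                {
                    "a": ("dysplastic", [np.full((1, 1), 0.3), np.full((1, 1), 0.5)]),
                    "b": ("dysplastic", [np.full((1, 1), 0.3), np.full((1, 1), 0.5)]),
                    "c": ("nondysplastic", [np.full((1, 1), 0.1), np.full((1, 1), 0.3)]),
                    "d": ("nondysplastic", [np.full((1, 1), 0.1), np.full((1, 1), 0.3)]),
                }
            ),
            area_groups=(1,),
        )
        # class means 0.4 vs 0.2, per-case population variances 0.01 and 0.01
        discs = derive_discriminants(stats, epsilon=0.0)
        assert discs.by_group[1].delta[0, 0] == pytest.approx(0.2)
        assert discs.by_group[1].d2[0, 0] == pytest.approx(0.04 / 0.01)

    def test_direct_evaluation_means_04_02_vars_001_003(self):
        # element-wise check straight from the definition
        delta = 0.4 - 0.2
        d2 = delta**2 / ((0.01 + 0.03) / 2)
        assert d2 == pytest.approx(2.0)

    def test_swapping_class_order_negates_delta_keeps_d2(self, rng):
        mats = {
            f"p{k}": (label, [rng.random((3, 3)) for _ in range(4)])
            for k, label in enumerate(
                ["dysplastic", "dysplastic", "nondysplastic", "nondysplastic"]
            )
        }
        stats = fit_class_statistics(_records(mats), area_groups=(1,))
        discs = derive_discriminants(stats)
        flipped = {
            pid: ("dysplastic" if lab == "nondysplastic" else "nondysplastic", m)
            for pid, (lab, m) in mats.items()
        }
        stats2 = fit_class_statistics(_records(flipped), area_groups=(1,))
        discs2 = derive_discriminants(stats2)
        np.testing.assert_allclose(
            discs.by_group[1].delta, -discs2.by_group[1].delta, atol=1e-12
        )
        np.testing.assert_allclose(discs.by_group[1].d2, discs2.by_group[1].d2, atol=1e-12)

    def test_zero_variance_nonzero_delta_uses_epsilon(self):
        stats = fit_class_statistics(
            _records(
                {
                    "a": ("dysplastic", [np.full((1, 1), 0.6)]),
                    "b": ("dysplastic", [np.full((1, 1), 0.6)]),
                    "c": ("nondysplastic", [np.full((1, 1), 0.4)]),
                    "d": ("nondysplastic", [np.full((1, 1), 0.4)]),
                }
            ),
            area_groups=(1,),
        )
        eps = 1e-8
        discs = derive_discriminants(stats, epsilon=eps)
        assert discs.by_group[1].d2[0, 0] == pytest.approx(0.2**2 / eps)


class TestNucleusFeatures:
    def test_hand_summation_oracle(self):
        P = np.array([[0.5, 0.1], [0.2, 0.2]])
        disc = AreaDiscriminant(
            delta=np.array([[1.0, -1.0], [1.0, -1.0]]),
            d2=np.array([[1.0, 2.0], [3.0, 4.0]]),
        )
        f_plus, f_minus = nucleus_features(P, disc)
        assert f_plus == pytest.approx(1.1)
        assert f_minus == pytest.approx(1.0)

    def test_all_positive_delta_empties_f_minus(self, rng):
        P = rng.random((4, 4))
        P /= P.sum()
        disc = AreaDiscriminant(delta=np.ones((4, 4)), d2=rng.random((4, 4)))
        assert nucleus_features(P, disc)[1] == 0.0

    def test_constant_d2_with_positive_delta_returns_the_constant(self, rng):
        P = rng.random((4, 4))
        P /= P.sum()
        disc = AreaDiscriminant(delta=np.ones((4, 4)), d2=np.full((4, 4), 3.5))
        assert nucleus_features(P, disc)[0] == pytest.approx(3.5)

    def test_zero_delta_elements_feed_neither_partition(self):
        P = np.full((2, 2), 0.25)
        disc = AreaDiscriminant(delta=np.zeros((2, 2)), d2=np.ones((2, 2)))
        assert nucleus_features(P, disc) == (0.0, 0.0)


class TestPatientFeatures:
    def _discs(self):
        d = DiscriminantMatrices()
        d.by_group[1] = AreaDiscriminant(delta=np.ones((1, 1)), d2=np.ones((1, 1)))
        return d

    def test_mean_over_eligible_nuclei(self):
        recs = [
            NucleusGlem("p", "dysplastic", 1, np.full((1, 1), v))
            for v in (1.0, 2.0, 6.0)
        ]
        pf = patient_features(recs, self._discs())
        assert pf.f_plus == pytest.approx(3.0)
        assert pf.n_nuclei_used == 3

    def test_single_eligible_nucleus(self):
        recs = [NucleusGlem("p", "dysplastic", 1, np.full((1, 1), 2.0))]
        pf = patient_features(recs, self._discs())
        assert pf.f_plus == pytest.approx(2.0)

    def test_nuclei_outside_a1_a5_excluded(self):
        recs = [
            NucleusGlem("p", "dysplastic", 0, np.full((1, 1), 100.0)),
            NucleusGlem("p", "dysplastic", 6, np.full((1, 1), 100.0)),
            NucleusGlem("p", "dysplastic", 1, np.full((1, 1), 2.0)),
        ]
        pf = patient_features(recs, self._discs())
        assert pf.f_plus == pytest.approx(2.0)
        assert pf.n_nuclei_used == 1

    def test_all_nuclei_in_a0_makes_patient_unscorable(self):
        recs = [NucleusGlem("p", "dysplastic", 0, np.full((1, 1), 1.0))]
        with pytest.warns(UserWarning, match="unscorable"):
            assert patient_features(recs, self._discs()) is None

    def test_f_diff_is_plus_minus_difference(self, rng):
        d = DiscriminantMatrices()
        d.by_group[2] = AreaDiscriminant(
            delta=rng.standard_normal((3, 3)), d2=rng.random((3, 3))
        )
        recs = [NucleusGlem("p", "dysplastic", 2, rng.random((3, 3))) for _ in range(4)]
        pf = patient_features(recs, d)
        assert pf.f_diff == pytest.approx(pf.f_plus - pf.f_minus, abs=1e-12)


def test_scaling_d2_scales_features_linearly(rng):
    d1 = DiscriminantMatrices()
    delta = rng.standard_normal((4, 4))
    d2 = rng.random((4, 4))
    d1.by_group[1] = AreaDiscriminant(delta=delta, d2=d2)
    d10 = DiscriminantMatrices()
    d10.by_group[1] = AreaDiscriminant(delta=delta, d2=10.0 * d2)
    recs = [
        NucleusGlem(f"p{k}", "dysplastic", 1, rng.random((4, 4))) for k in range(3)
    ]
    t1 = feature_table(recs, d1)
    t10 = feature_table(recs, d10)
    np.testing.assert_allclose(10.0 * t1["f_plus"], t10["f_plus"], rtol=1e-12)
    np.testing.assert_allclose(10.0 * t1["f_minus"], t10["f_minus"], rtol=1e-12)
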