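import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from ki67tma import (
    agreement_report,
    agreement_trend,
    compare_auc,
    compare_kappa,
    dichotomize,
    extreme_discrepancy,
    nuclei_bin,
    observed_agreement,
    quartile_bin,
    roc_auc,
    subject_average,
    weighted_kappa,
)
from ki67tma.agreement import linear_weighted_kappa_point


def brute_force_weighted_kappa(a, b, k):
    """Independent evaluation of the linear-weight formula, loop by loop."""
    n = len(a)
    joint = np.zeros((k, k))
    for x, y in zip(a, b):
        joint[x - 1, y - 1] += 1.0 / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 - abs(i - j) / (k - 1)
            po += w * joint[i, j]
            pe += w * pa[i] * pb[j]
    return (po - pe) / (1.0 - pe)


def brute_force_auc(scores, labels):
    """O(n^2) Mann-Whitney probability with half credit for ties."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestQuartileBin:
    def test_four_distinct_values(self):
        cats, bounds = quartile_bin(np.array([1.0, 2.0, 3.0, 4.0]))
        assert cats.tolist() == [1, 2, 3, 4]
        assert bounds.tolist() == [1.75, 2.5, 3.25]

    def test_boundary_value_goes_to_q2(self):
        scores = np.arange(101, dtype=float)  # 25th percentile = 25.0 exactly
        cats, bounds = quartile_bin(scores)
        assert bounds[0] == 25.0
        assert cats[25] == 2
        assert cats[24] == 1
        assert cats[50] == 2  # 50th percentile itself stays in Q2
        assert cats[51] == 3

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            cats, _ = quartile_bin(np.full(10, 7.0))
        assert (cats == 1).all()

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            quartile_bin(np.array([1.0, np.nan]))


class TestWeightedKappa:
    def test_identical_ratings(self):
        a = np.array([1, 2, 3, 4, 2, 3])
        assert linear_weighted_kappa_point(a, a, 4) == pytest.approx(1.0)

    def test_margin_product_table_gives_zero(self):
        # joint table equal to the product of its margins -> po == pe
        a = np.repeat([1, 1, 2, 2], [6, 4, 6, 4])
        b = np.tile([1, 1, 1, 2, 2], 4)
        joint = np.zeros((2, 2))
        np.add.at(joint, (a - 1, b - 1), 1)
        assert np.allclose(joint, np.outer(joint.sum(1), joint.sum(0)) / joint.sum())
        assert linear_weighted_kappa_point(a, b, 2) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        # 2x2 table a=40, b=10, c=10, d=40 -> kappa = (0.8-0.5)/(1-0.5) = 0.6
        a = np.repeat([1, 1, 2, 2], [40, 10, 10, 40])
        b = np.repeat([1, 2, 1, 2], [40, 10, 10, 40])
        assert linear_weighted_kappa_point(a, b, 2) == pytest.approx(0.6)

    def test_equals_sklearn_linear_weights(self, rng):
        for _ in range(25):
            a = rng.integers(1, 5, 80)
            b = rng.integers(1, 5, 80)
            ours = linear_weighted_kappa_point(a, b, 4)
            ref = cohen_kappa_score(a, b, labels=[1, 2, 3, 4], weights="linear")
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_symmetry_and_k2_equals_unweighted(self, rng):
        a = rng.integers(1, 3, 60)
        b = rng.integers(1, 3, 60)
        assert linear_weighted_kappa_point(a, b, 2) == pytest.approx(
            linear_weighted_kappa_point(b, a, 2)
        )
        assert linear_weighted_kappa_point(a, b, 2) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_ci_contains_point_and_is_seeded(self, rng):
        a = rng.integers(1, 5, 100)
        b = np.where(rng.random(100) < 0.7, a, rng.integers(1, 5, 100))
        r1 = weighted_kappa(a, b, 4, n_boot=200, seed=5)
        r2 = weighted_kappa(a, b, 4, n_boot=200, seed=5)
        assert r1["ci"] == r2["ci"]
        assert r1["ci"][0] <= r1["kappa"] <= r1["ci"][1]

    def test_validation(self):
        with pytest.raises(ValueError):
            weighted_kappa([1, 2], [1])
        with pytest.raises(ValueError):
            weighted_kappa([], [])


class TestObservedAgreement:
    def test_trivial_cases(self):
        a = np.array([1, 2, 3, 4])
        assert observed_agreement(a, a, n_boot=10)["agreement"] == 100.0
        assert observed_agreement(a, np.array([1, 2, 4, 3]), n_boot=10)["agreement"] == 50.0
        assert observed_agreement(a, 5 - a, n_boot=10)["agreement"] == 0.0

    def test_matches_direct_count(self, rng):
        a = rng.integers(1, 5, 200)
        b = rng.integers(1, 5, 200)
        expected = 100.0 * sum(x == y for x, y in zip(a, b)) / 200
        assert observed_agreement(a, b, n_boot=10)["agreement"] == pytest.approx(expected)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        assert roc_auc(scores, labels)["auc"] == pytest.approx(1.0)

    def test_all_ties_gives_half(self):
        scores = np.ones(10)
        labels = np.array([0, 1] * 5, bool)
        assert roc_auc(scores, labels)["auc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, bool))

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            scores = np.round(rng.random(60), 2)  # rounding forces ties
            labels = rng.random(60) < 0.4
            if labels.all() or (~labels).all():
                continue
            assert roc_auc(scores, labels)["auc"] == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance_and_reflection(self, rng):
        scores = rng.random(80)
        labels = rng.random(80) < 0.5
        base = roc_auc(scores, labels)["auc"]
        assert roc_auc(np.exp(3 * scores), labels)["auc"] == pytest.approx(base, abs=1e-12)
        assert roc_auc(-scores, labels)["auc"] == pytest.approx(1 - base, abs=1e-12)

    def test_dichotomize_cutoff_inclusive(self):
        assert dichotomize([9.9, 10.0, 10.1]).tolist() == [False, True, True]


class TestCompareAuc:
    def test_identical_scores_null(self, rng):
        scores = rng.random(50)
        labels = rng.random(50) < 0.5
        res = compare_auc(scores, scores, labels)
        assert res["delta_auc"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_null_p_values_roughly_uniform(self):
        """Permuted scorer B against A: DeLong p should be ~Uniform(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(300):
            labels = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
            base = rng.random(40) + 0.8 * labels
            noise_a = base + rng.normal(0, 0.3, 40)
            noise_b = base + rng.normal(0, 0.3, 40)
            pvals.append(compare_auc(noise_a, noise_b, labels)["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_power_against_random_scorer(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(40):
            labels = rng.random(200) < 0.5
            strong = labels + rng.normal(0, 0.3, 200)
            random_scorer = rng.random(200)
            if compare_auc(strong, random_scorer, labels)["p_value"] < 0.05:
                rejections += 1
        assert rejections >= 38  # >= 95 % power

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            compare_auc(np.arange(5.0), np.arange(4.0), np.array([0, 1, 0, 1, 0], bool))


class TestCompareKappa:
    def test_identical_strata(self, rng):
        a = rng.integers(1, 5, 120)
        b = np.where(rng.random(120) < 0.7, a, rng.integers(1, 5, 120))
        res = compare_kappa(a, b, a, b, 4, n_boot=200, seed=1)
        assert res["delta_kappa"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] > 0.9

    def test_sign_flip_on_swap(self, rng):
        a1 = rng.integers(1, 5, 80)
        b1 = a1.copy()
        a2 = rng.integers(1, 5, 80)
        b2 = rng.integers(1, 5, 80)
        r12 = compare_kappa(a1, b1, a2, b2, 4, n_boot=200, seed=3)
        r21 = compare_kappa(a2, b2, a1, b1, 4, n_boot=200, seed=3)
        assert r12["delta_kappa"] == pytest.approx(-r21["delta_kappa"], abs=0.05)

    def test_detects_noise_difference(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(10):
            truth1 = rng.integers(1, 5, 400)
            clean = np.where(rng.random(400) < 0.9, truth1, rng.integers(1, 5, 400))
            truth2 = rng.integers(1, 5, 400)
            noisy = np.where(rng.random(400) < 0.4, truth2, rng.integers(1, 5, 400))
            res = compare_kappa(truth1, clean, truth2, noisy, 4, n_boot=200, seed=2)
            if res["p_value"] < 0.05 and res["delta_kappa"] > 0:
                hits += 1
        assert hits >= 9

    def test_small_stratum_refused(self):
        with pytest.raises(ValueError):
            compare_kappa([1, 2, 3], [1, 2, 3], [1] * 20, [1] * 20)


class TestNucleiBin:
    @pytest.mark.parametrize(
        "total, label",
        [(50, "50-500"), (500, "50-500"), (501, ">500-1,000"), (4500, ">4,000-4,500"),
         (4501, ">4,500"), (10_000, ">4,500")],
    )
    def test_bin_edges(self, total, label):
        assert nuclei_bin([total])[0] == label

    def test_below_qc_floor_rejected(self):
        with pytest.raises(ValueError):
            nuclei_bin([49])


class TestAgreementTrend:
    def test_perfect_monotone(self):
        res = agreement_trend([250, 750, 1250, 1750], [0.2, 0.4, 0.6, 0.8])
        assert res["r"] == pytest.approx(1.0)
        noisy = agreement_trend([100, 500, 1000, 2000], [0.2, 0.45, 0.58, 0.8])
        assert noisy["r"] > 0.9

    def test_constant_metric_flagged(self):
        res = agreement_trend([100, 500, 1000], [0.5, 0.5, 0.5])
        assert res["degenerate"]

    def test_too_few_bins_refused(self):
        with pytest.raises(ValueError):
            agreement_trend([1, 2], [0.1, 0.2])


class TestExtremeDiscrepancy:
    def test_identical_is_zero(self):
        cats = np.array([1, 2, 3, 4] * 5)
        assert extreme_discrepancy(cats, cats)["rate_percent"] == 0.0

    def test_constructed_two_percent(self):
        a = np.ones(100, dtype=int)
        b = np.ones(100, dtype=int)
        a[:2], b[:2] = 1, 4
        assert extreme_discrepancy(a, b)["rate_percent"] == pytest.approx(2.0)

    def test_matches_direct_count(self, rng):
        a = rng.integers(1, 5, 300)
        b = rng.integers(1, 5, 300)
        expected = 100 * sum((x, y) in ((1, 4), (4, 1)) for x, y in zip(a, b)) / 300
        assert extreme_discrepancy(a, b)["rate_percent"] == pytest.approx(expected)


class TestSubjectAverage:
    def test_simple_mean(self):
        table = pd.DataFrame(
            {"subject_id": ["s1", "s1", "s2"], "core_id": ["a", "b", "c"], "score": [10.0, 20.0, 7.0]}
        )
        out = subject_average(table)
        assert dict(zip(out["subject_id"], out["score"])) == {"s1": 15.0, "s2": 7.0}

    def test_excluded_core_dropped_from_mean(self):
        table = pd.DataFrame(
            {
                "subject_id": ["s1"] * 3,
                "core_id": ["a", "b", "c"],
                "score": [10.0, 20.0, 90.0],
            }
        )
        out = subject_average(table, passing_core_ids={"a", "b"})
        assert out["score"].iloc[0] == pytest.approx(15.0)

    def test_subject_without_passing_cores_dropped_and_counted(self):
        table = pd.DataFrame(
            {"subject_id": ["s1", "s2"], "core_id": ["a", "b"], "score": [10.0, 20.0]}
        )
        out = subject_average(table, passing_core_ids={"a"})
        assert out["subject_id"].tolist() == ["s1"]
        assert out.attrs["n_subjects_dropped"] == 1


def test_agreement_report_end_to_end(rng):
    auto = rng.uniform(0, 50, 120)
    visual = np.clip(auto + rng.normal(0, 3, 120), 0, 100)
    strata = np.where(rng.random(120) < 0.5, "satisfactory", "suboptimal")
    report = agreement_report(auto, visual, strata=strata, n_boot=100, seed=0)
    assert report.n == 120
    assert -1 <= report.kappa <= 1
    assert 0 <= report.agreement_percent <= 100
    assert report.auc is not None and 0.5 < report.auc <= 1
    assert set(report.strata) == {"satisfactory", "suboptimal"}
    d = report.to_dict()
    assert "strata" in d and d["n"] == 120
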