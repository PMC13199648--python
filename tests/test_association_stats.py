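"""The association battery against independent oracles and SciPy/sklearn."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import icpburden as ib
from icpburden.exceptions import DegenerateDataError


def midranks(x):
    """Independent midrank routine: average position of each tied value."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestCorrelation:
    def test_spearman_perfect_monotone(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert ib.spearman(x, x).statistic == pytest.approx(1.0)
        assert ib.spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_spearman_equals_pearson_on_midranks_with_ties(self, rng):
        x = rng.integers(0, 5, size=10).astype(float)
        y = rng.integers(0, 4, size=10).astype(float)
        r = ib.spearman(x, y).statistic
        oracle = ib.pearson(midranks(x), midranks(y)).statistic
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_spearman_matches_scipy(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        ours = ib.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_pearson_linear_and_orthogonal(self, rng):
        x = rng.normal(size=12)
        assert ib.pearson(x, 2 * x + 3).statistic == pytest.approx(1.0)
        y = rng.normal(size=12)
        y_orth = y - y.mean() - (x - x.mean()) * ((y - y.mean()) @ (x - x.mean())) / (
            (x - x.mean()) @ (x - x.mean())
        )
        assert ib.pearson(x, y_orth).statistic == pytest.approx(0.0, abs=1e-12)

    def test_pearson_matches_textbook_formula_and_scipy(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        ours = ib.pearson(x, y)
        assert ours.statistic == pytest.approx(num / den, abs=1e-12)
        ref = sps.pearsonr(x, y)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateDataError):
            ib.pearson([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestTTests:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = ib.welch_t(a, a.copy())
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_large_separation(self):
        a = np.array([0.0, 0.01, 0.02, 0.0, 0.01])
        res = ib.welch_t(a, a + 100.0)
        assert res.p_value < 1e-6

    def test_matches_scipy_and_quadrature(self, rng):
        a = rng.normal(0, 1, size=9)
        b = rng.normal(0.8, 2, size=14)
        ours = ib.welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        df = ours.details["df"]
        tail, _ = integrate.quad(lambda u: sps.t.pdf(u, df), abs(ours.statistic), np.inf)
        assert ours.p_value == pytest.approx(2 * tail, rel=1e-6)

    def test_student_variant_matches_scipy(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=10)
        ref = sps.ttest_ind(a, b, equal_var=True)
        ours = ib.student_t(a, b)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            ib.welch_t([5.0, 5.0], [5.0, 5.0])


class TestChiSquare:
    def test_closed_form_examples(self):
        assert ib.chi_square_2x2([[10, 0], [0, 10]]).statistic == pytest.approx(20.0)
        res = ib.chi_square_2x2([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_matches_generic_expected_count_oracle(self, rng):
        for _ in range(50):
            tab = rng.integers(1, 30, size=(2, 2)).astype(float)
            expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            oracle = float(((tab - expected) ** 2 / expected).sum())
            assert ib.chi_square_2x2(tab).statistic == pytest.approx(oracle, rel=1e-12)

    def test_invariance_under_transpose_and_swaps(self, rng):
        tab = rng.integers(1, 20, size=(2, 2))
        base = ib.chi_square_2x2(tab).statistic
        for variant in (tab.T, tab[::-1], tab[:, ::-1]):
            assert ib.chi_square_2x2(variant).statistic == pytest.approx(base, rel=1e-12)

    def test_matches_scipy_with_and_without_yates(self, rng):
        tab = rng.integers(2, 25, size=(2, 2))
        for yates in (False, True):
            ref_stat, ref_p, _, _ = sps.chi2_contingency(tab, correction=yates)[:4]
            ours = ib.chi_square_2x2(tab, yates=yates)
            assert ours.statistic == pytest.approx(ref_stat, rel=1e-12)
            assert ours.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_zero_marginal_raises_with_message(self):
        with pytest.raises(DegenerateDataError, match="marginal"):
            ib.chi_square_2x2([[0, 0], [3, 4]])


class TestMannWhitney:
    def test_complete_separation_min_u_zero(self):
        res = ib.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_identical_multisets_give_central_u(self):
        res = ib.mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.statistic == 4 * 4 / 2

    def test_exact_p_matches_brute_force_enumeration(self, rng):
        vals = rng.choice(100, size=8, replace=False).astype(float)
        a, b = vals[:4], vals[4:]
        res = ib.mann_whitney_u(a, b, exact=True)
        n = 8
        count = total = 0
        ranks = sps.rankdata(vals)
        for subset in itertools.combinations(range(n), 4):
            ua = ranks[list(subset)].sum() - 4 * 5 / 2
            u = min(ua, 16 - ua)
            total += 1
            count += u <= res.statistic
        assert res.p_value == pytest.approx(count / total, abs=1e-12)
        assert res.details["method"] == "exact"

    def test_exact_p_matches_scipy_exact(self, rng):
        vals = rng.choice(50, size=11, replace=False).astype(float)
        a, b = vals[:5], vals[5:]
        ours = ib.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_data_uses_corrected_normal_approximation(self, rng):
        a = rng.integers(0, 6, size=15).astype(float)
        b = rng.integers(1, 7, size=18).astype(float)
        ours = ib.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic", alternative="two-sided")
        assert ours.details["method"] == "normal_approx"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestRoc:
    def test_perfect_separation(self):
        res = ib.roc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert res.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        res = ib.roc([1.0] * 6, [True, False, True, False, False, True])
        assert res.auc == pytest.approx(0.5)

    def test_auc_equals_concordance_probability(self, rng):
        for _ in range(30):
            scores = rng.integers(0, 4, size=30).astype(float)  # heavy ties
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            gt = (pos[:, None] > neg[None, :]).sum()
            eq = (pos[:, None] == neg[None, :]).sum()
            conc = (gt + 0.5 * eq) / (pos.size * neg.size)
            assert ib.roc(scores, labels).auc == pytest.approx(conc, abs=1e-12)

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.3
        assert ib.roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_shape(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        res = ib.roc(scores, labels)
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateDataError):
            ib.roc([1.0, 2.0], [True, True])


class TestHolm:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        pvals = {f"t{i}": float(p) for i, p in enumerate(rng.random(8))}
        ours = ib.holm_adjust(pvals)
        _, ref, _, _ = multipletests(list(pvals.values()), method="holm")
        for name, p_adj in zip(pvals, ref):
            assert ours[name] == pytest.approx(p_adj, abs=1e-12)


class TestSuite:
    def test_near_separable_cohort_has_high_roc_auc(self, cohort200_rule):
        cohort, summaries = cohort200_rule
        report = ib.run_association_suite(summaries, cohort.outcomes)
        assert report.rocs["normalized_auc"].auc >= 0.95
        assert report.tests["spearman:normalized_auc"].p_value < 1e-6

    def test_all_survivor_cohort_marks_tests_not_computable(self, small_cohort):
        _, summaries = small_cohort
        outcomes = {pid: ib.OutcomeRecord(pid, 2) for pid in summaries}
        report = ib.run_association_suite(summaries, outcomes)
        for key, res in report.tests.items():
            assert not res.computable, key
        assert report.rocs == {}

    def test_report_structure_and_serialization(self, small_cohort):
        cohort, summaries = small_cohort
        report = ib.run_association_suite(summaries, cohort.outcomes, holm=True)
        for metric in ("normalized_auc", "max_icp", "mean_icp", "frac_above_20", "dose_above_15"):
            for test in ("spearman", "pearson", "t_test", "mann_whitney"):
                assert f"{test}:{metric}" in report.tests
        assert "chi2:frac_above_20_gt_0.3" in report.tests
        d = report.to_dict()
        assert d["n_patients"] == 30
        assert set(d) >= {"tests", "rocs", "holm_adjusted_p"}
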