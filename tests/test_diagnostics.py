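"""Statistical machinery: ROC/DeLong, cutoff, exact CIs, ICC, Grubbs, suite."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mcpratio as m
from mcpratio.diagnostics import DegenerateVarianceError, DiagnosticsError


def pairwise_auc_oracle(scores, labels, direction="lower"):
    """Tie-corrected pairwise-comparison probability, computed by loops."""
    s = np.asarray(scores, float)
    s = -s if direction == "lower" else s
    pos = s[np.asarray(labels, bool)]
    neg = s[~np.asarray(labels, bool)]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = m.roc_auc([0.01, 0.02, 0.5, 0.6], [True, True, False, False],
                        "lower")
        assert roc.auc == 1.0

    def test_toy_with_tie(self):
        roc = m.roc_auc([0.05, 0.10, 0.10, 0.20],
                        [True, True, False, False], "lower")
        assert roc.auc == pytest.approx(0.875)   # (3 + 0.5) / 4

    def test_curve_shape_contracts(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        roc = m.roc_auc(scores, labels, "lower")
        assert roc.tpr[0] == roc.fpr[0] == 0.0
        assert roc.tpr[-1] == roc.fpr[-1] == 1.0
        assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()
        assert 0.0 <= roc.auc <= 1.0

    def test_trapezoid_equals_pairwise_probability_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.normal(size=n), 1)   # induces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = m.roc_auc(scores, labels, "lower")
            trap = np.trapezoid(roc.tpr, roc.fpr)
            oracle = pairwise_auc_oracle(scores, labels, "lower")
            assert roc.auc == pytest.approx(oracle, abs=1e-12)
            assert trap == pytest.approx(oracle, abs=1e-12)

    def test_direction_flip_complements_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        lo = m.roc_auc(scores, labels, "lower").auc
        hi = m.roc_auc(scores, labels, "higher").auc
        assert lo + hi == pytest.approx(1.0)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        scores = np.round(rng.normal(size=60), 1)
        labels = rng.random(60) < 0.5
        ours = m.roc_auc(scores, labels, "higher").auc
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DiagnosticsError):
            m.roc_auc([1.0, 2.0], [True, True], "lower")


class TestDeLong:
    def test_identical_scores_give_null_result(self):
        scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        labels = [True, True, True, False, False, False]
        z, p = m.delong(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_variance_matches_hand_structural_components(self):
        """5-subject toy: SE^2 from an explicit loop implementation."""
        scores = np.array([0.05, 0.12, 0.08, 0.20, 0.15])
        labels = np.array([True, True, True, False, False])
        s = -scores
        pos, neg = s[labels], s[~labels]
        v10 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                 for q in neg]) for p in pos])
        v01 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                 for p in pos]) for q in neg])
        var = np.var(v10, ddof=1) / 3 + np.var(v01, ddof=1) / 2
        roc = m.roc_auc(scores, labels, "lower")
        assert roc.auc_se ** 2 == pytest.approx(var, abs=1e-15)
        assert roc.auc == pytest.approx(v10.mean())

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(123)
        n_pos, n_neg = 20, 30
        pos = rng.normal(0.07, 0.06, n_pos)
        neg = rng.normal(0.17, 0.05, n_neg)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
        delong_var = m.roc_auc(scores, labels, "lower").auc_se ** 2
        boots = np.empty(10_000)
        for b in range(boots.size):
            rp = pos[rng.integers(0, n_pos, n_pos)]
            rn = neg[rng.integers(0, n_neg, n_neg)]
            diff = rp[:, None] - rn[None, :]
            boots[b] = ((diff < 0) + 0.5 * (diff == 0)).mean()
        assert delong_var == pytest.approx(boots.var(ddof=1), rel=0.15)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        ci0 = m.auc_ci(scores, labels, "lower")
        ci1 = m.auc_ci(np.exp(scores) * 3 - 1, labels, "lower")
        assert ci0 == pytest.approx(ci1, abs=1e-12)

    def test_detects_better_marker(self):
        rng = np.random.default_rng(9)
        n = 200
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        strong = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        weak = strong + rng.normal(0, 2.0, 2 * n)
        z, p = m.delong(strong, weak, labels)
        assert p < 0.01
        # the test statistic is symmetric
        z2, p2 = m.delong(weak, strong, labels)
        assert z2 == pytest.approx(-z) and p2 == pytest.approx(p)


class TestOptimalCutoff:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = m.roc_auc(scores, labels, "lower")
            cut = m.optimal_cutoff(roc)
            finite = np.isfinite(roc.thresholds)
            dists = np.hypot(1 - roc.tpr[finite], roc.fpr[finite])
            assert np.hypot(1 - cut.sensitivity, 1 - cut.specificity) \
                == pytest.approx(dists.min(), abs=1e-12)

    def test_perfect_separation_reaches_corner(self):
        roc = m.roc_auc([0.01, 0.02, 0.5, 0.6], [True, True, False, False],
                        "lower")
        cut = m.optimal_cutoff(roc)
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0
        assert 0.02 < cut.threshold < 0.5

    def test_operating_point_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        c0 = m.optimal_cutoff(m.roc_auc(scores, labels, "lower"))
        c1 = m.optimal_cutoff(m.roc_auc(np.tanh(scores) * 7, labels, "lower"))
        assert c0.sensitivity == c1.sensitivity
        assert c0.specificity == c1.specificity

    def test_simulated_operating_point_near_reported(self):
        """Cutoffs on Normal(0.07,0.06) n=32 vs Normal(0.17,0.03) n=8 cohorts
        land near the reported sens 0.906 / spec 0.875 on average."""
        rng = np.random.default_rng(77)
        sens, spec = [], []
        for _ in range(300):
            scores = np.concatenate([rng.normal(0.07, 0.06, 32),
                                     rng.normal(0.17, 0.03, 8)])
            labels = np.concatenate([np.ones(32, bool), np.zeros(8, bool)])
            cut = m.optimal_cutoff(m.roc_auc(scores, labels, "lower"))
            sens.append(cut.sensitivity)
            spec.append(cut.specificity)
        assert np.mean(sens) == pytest.approx(0.906, abs=0.1)
        assert np.mean(spec) == pytest.approx(0.875, abs=0.1)


class TestClopperPearson:
    def test_boundary_cases(self):
        assert m.clopper_pearson(0, 10)[0] == 0.0
        assert m.clopper_pearson(10, 10)[1] == 1.0
        lo, hi = m.clopper_pearson(10, 10)
        assert lo == pytest.approx((0.025) ** (1 / 10))

    def test_published_interval(self):
        lo, hi = m.clopper_pearson(29, 32)
        assert round(lo, 3) == 0.750 and round(hi, 3) == 0.980

    @staticmethod
    def _oracle(x, n, alpha=0.05):
        """Bisection on binomial tail sums, independent of beta quantiles."""
        def upper_tail(p):   # P(X >= x | p), increasing in p
            return float(stats.binom.pmf(np.arange(x, n + 1), n, p).sum())

        def lower_tail_flip(p):   # P(X <= x | 1-p), increasing in p
            return float(stats.binom.pmf(np.arange(0, x + 1), n, 1.0 - p).sum())

        def bisect_increasing(f, target, lo, hi):
            for _ in range(60):
                mid = (lo + hi) / 2
                if f(mid) < target:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2
        lo = 0.0 if x == 0 else bisect_increasing(upper_tail, alpha / 2,
                                                  1e-12, 1 - 1e-12)
        hi = 1.0 if x == n else 1.0 - bisect_increasing(
            lower_tail_flip, alpha / 2, 1e-12, 1 - 1e-12)
        return lo, hi

    @settings(max_examples=40)
    @given(n=st.integers(1, 50), frac=st.floats(0.0, 1.0))
    def test_agrees_with_tail_sum_oracle(self, n, frac):
        x = int(round(frac * n))
        lo, hi = m.clopper_pearson(x, n)
        olo, ohi = self._oracle(x, n)
        assert lo == pytest.approx(olo, abs=1e-6)
        assert hi == pytest.approx(ohi, abs=1e-6)

    def test_invalid_counts_rejected(self):
        with pytest.raises(DiagnosticsError):
            m.clopper_pearson(5, 3)


class TestConfusionMetrics:
    def test_reviewer_one_msa_vs_sca3(self):
        table = m.ConfusionTable(tp=29, fn=3, fp=2, tn=6)
        s = m.confusion_metrics(table)
        assert s.sensitivity.pct == pytest.approx(90.6, abs=0.051)
        assert s.specificity.pct == pytest.approx(75.0, abs=0.051)
        assert s.ppv.pct == pytest.approx(93.5, abs=0.051)
        assert s.npv.pct == pytest.approx(66.7, abs=0.051)
        assert s.accuracy.pct == pytest.approx(87.5, abs=0.051)
        assert s.sensitivity.ci_lo_pct == pytest.approx(75.0, abs=0.051)
        assert s.sensitivity.ci_hi_pct == pytest.approx(98.0, abs=0.051)

    def test_perfect_table_closed_form_lower_bound(self):
        table = m.ConfusionTable(tp=16, fn=0, fp=0, tn=16)
        s = m.confusion_metrics(table)
        for est, n in ((s.sensitivity, 16), (s.specificity, 16),
                       (s.accuracy, 32)):
            assert est.pct == 100.0
            assert est.ci_lo_pct == pytest.approx(
                100.0 * 0.025 ** (1.0 / n), abs=1e-9)
            assert est.pct <= est.ci_hi_pct and est.pct >= est.ci_lo_pct

    def test_zero_denominator_reported_as_undefined(self):
        table = m.ConfusionTable(tp=0, fn=8, fp=0, tn=16)
        s = m.confusion_metrics(table)
        assert s.ppv is None
        assert s.sensitivity.pct == 0.0

    def test_point_estimate_inside_its_ci(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = m.ConfusionTable(*(int(v) for v in rng.integers(0, 30, 4)))
            if t.tp + t.fn == 0 or t.tn + t.fp == 0:
                continue
            s = m.confusion_metrics(t)
            for est in (s.sensitivity, s.specificity, s.accuracy):
                assert est.ci_lo_pct - 1e-9 <= est.pct <= est.ci_hi_pct + 1e-9

    def test_full_published_table_reproduced(self):
        df = m.reviewer_performance_check()
        assert len(df) == 132
        assert (df["abs_diff"] <= 0.05 + 1e-9).all()


class TestBinomialAccuracy:
    def test_upper_boundary(self):
        assert m.binomial_accuracy_test(40, 40, 0.9) == pytest.approx(1.0)

    def test_matches_direct_tail_summation(self):
        p = m.binomial_accuracy_test(32, 40, 0.90)
        direct = sum(stats.binom.pmf(k, 40, 0.90) for k in range(33))
        assert p == pytest.approx(direct, abs=1e-12)
        assert round(p, 3) == 0.042   # the reported comparison value

    def test_two_sided_at_least_one_sided(self):
        one = m.binomial_accuracy_test(32, 40, 0.9, "lower")
        two = m.binomial_accuracy_test(32, 40, 0.9, "two")
        assert two >= one


class TestIcc:
    def test_identical_raters_give_unity(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[:, None], (1, 3))
        assert m.icc(x).icc == pytest.approx(1.0)

    def test_rater_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3))
        a = m.icc(x).icc
        b = m.icc(x[:, [2, 0, 1]]).icc
        assert a == pytest.approx(b, abs=1e-12)

    def test_toy_matrix_matches_hand_anova(self):
        """4x3 matrix against explicitly computed two-way mean squares."""
        x = np.array([[9.0, 2.0, 5.0],
                      [6.0, 1.0, 3.0],
                      [8.0, 4.0, 6.0],
                      [7.0, 1.0, 2.0]])
        n, k = x.shape
        grand = x.mean()
        msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
        msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
        sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
                  for i in range(n) for j in range(k))
        mse = sse / ((n - 1) * (k - 1))
        expect2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        expect3 = (msr - mse) / (msr + (k - 1) * mse)
        assert m.icc(x, "icc2_1").icc == pytest.approx(expect2, abs=1e-12)
        assert m.icc(x, "icc3_1").icc == pytest.approx(expect3, abs=1e-12)

    def test_pingouin_cross_check(self):
        import pingouin as pg
        rng = np.random.default_rng(14)
        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        df = pd.DataFrame(x, columns=["r1", "r2", "r3"])
        long = df.reset_index().melt(id_vars="index", var_name="rater",
                                     value_name="score")
        table = pg.intraclass_corr(long, targets="index", raters="rater",
                                   ratings="score")
        # ICC(A,1): two-way random absolute agreement; ICC(C,1): consistency
        icc2 = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        icc3 = float(table.loc[table["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert m.icc(x, "icc2_1").icc == pytest.approx(icc2, abs=1e-9)
        assert m.icc(x, "icc3_1").icc == pytest.approx(icc3, abs=1e-9)

    def test_zero_between_subject_variance_flagged(self):
        x = np.zeros((5, 3))
        res = m.icc(x)
        assert res.degenerate and np.isnan(res.icc)


class TestGrubbs:
    def test_three_point_series(self):
        rep = m.grubbs([1.0, 2.0, 3.0])
        assert rep.g_statistic == pytest.approx(1.0)
        assert rep.critical_value == pytest.approx(1.1543, abs=1e-4)
        assert rep.flagged_index is None

    def test_gross_outlier_flagged(self):
        rep = m.grubbs([1.0, 2.0, 3.0, 50.0])
        assert rep.flagged_index == 3

    def test_critical_value_matches_closed_form(self):
        for n in range(3, 31):
            t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
            expect = (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))
            assert m.grubbs_critical_value(n) == pytest.approx(expect, abs=1e-12)

    def test_iterative_mode_retests_reduced_series(self):
        values = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 8.0, 4.5]
        rep = m.grubbs(values, iterative=True)
        assert rep.removed_indices == [6, 7]   # extreme first, then the next
        assert rep.flagged_index is None
        # single-pass mode flags only the most extreme point
        single = m.grubbs(values)
        assert single.flagged_index == 6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DiagnosticsError):
            m.grubbs([1.0, 2.0])
        with pytest.raises(DiagnosticsError):
            m.grubbs([3.0, 3.0, 3.0])


class TestGroupComparisons:
    def test_bonferroni_threshold_for_three_pairs(self):
        assert m.bonferroni_alpha(3) == pytest.approx(0.0167, abs=5e-5)

    def test_mannwhitney_matches_full_enumeration(self):
        x = np.array([1.2, 3.4, 2.2, 5.0])
        y = np.array([0.5, 0.9, 2.8, 1.7])
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        pooled = np.concatenate([x, y])
        n1 = len(x)
        u_obs = res.statistic

        def u_stat(first):
            rest = [v for i, v in enumerate(pooled) if i not in first]
            a = pooled[list(first)]
            return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in rest)
        us = [u_stat(c) for c in itertools.combinations(range(8), n1)]
        extreme = np.mean([min(u, n1 * 4 - u) <= min(u_obs, n1 * 4 - u_obs)
                           for u in us])
        assert res.pvalue == pytest.approx(extreme, abs=1e-12)

    def test_spearman_of_monotone_pairing_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        df = pd.DataFrame({
            "group": ["MSA-C"] * 5, "mcp_ratio": x,
            "mcp_volume_norm": x ** 3, "age": np.linspace(50, 70, 5),
            "extent_score": [3, 2, 2, 1, 0],
        })
        report = m.group_comparisons(
            df, patient_groups=("MSA-C",), index_group="MSA-C")
        # extent decreases with the ratio here -> Spearman rho = -1
        assert report["spearman_extent_ratio"]["r"] == pytest.approx(-0.973,
                                                                     abs=0.03)
        rho, _ = stats.spearmanr(x, x ** 3)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_full_suite_on_simulated_cohort(self):
        cohort = m.simulate_value_cohort(m.CohortSpec(seed=3))
        report = m.group_comparisons(cohort)
        assert report["bonferroni_alpha"] == pytest.approx(0.05 / 3)
        assert {"sex_chi2", "age_anova", "duration_kruskal",
                "duration_pairwise", "ratio_ancova", "volume_ancova",
                "spearman_extent_ratio",
                "pearson_ratio_volume"} <= report.keys()
        # the simulated group separation is strong for the ratio
        assert report["ratio_ancova"]["p"] < 1e-6
        assert report["spearman_extent_ratio"]["r"] < 0
        assert report["pearson_ratio_volume"]["r"] > 0
        assert len(report["duration_pairwise"]) == 3
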