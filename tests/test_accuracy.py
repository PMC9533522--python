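"""Accuracy primitives: confusion tables, exact intervals, ROC/AUC,
DeLong variance, Youden selection, and the enumeration oracles."""

import numpy as np
import pytest
from scipy import stats

from airwayus import (
    ScorePmf,
    auc_mann_whitney,
    confusion_table,
    delong_auc,
    delong_paired,
    empirical_roc,
    pmf_auc,
    predictive_values,
    proportion_ci,
    sample_indicators,
    score_pmf,
    score_pmf_correlated,
    youden_from_pmfs,
    youden_optimal,
)

DTI_CASE_RATES = (0.81, 0.77, 0.78)
DTI_CONTROL_RATES = (0.20, 0.25, 0.39)


class TestConfusionTable:
    def test_perfect_agreement(self):
        ct = confusion_table([True, False], [True, False])
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (1, 0, 0, 1)

    def test_all_negative_predictions(self):
        labels = [True] * 3 + [False] * 7
        ct = confusion_table([False] * 10, labels)
        assert (ct.fn, ct.tn) == (3, 7)
        assert ct.n_cases == 3 and ct.n_controls == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_table([], [])


class TestProportionCI:
    def test_boundaries(self):
        lo = proportion_ci(0, 10)
        assert lo.point == 0.0 and lo.ci_low == 0.0
        hi = proportion_ci(10, 10)
        assert hi.point == 1.0 and hi.ci_high == 1.0

    def test_exact_beta_quantiles(self):
        """Clopper-Pearson bounds are the exact beta quantiles."""
        est = proportion_ci(22, 26)
        assert est.ci_low == pytest.approx(stats.beta.ppf(0.025, 22, 5), abs=1e-12)
        assert est.ci_high == pytest.approx(stats.beta.isf(0.025, 23, 4), abs=1e-12)
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (0.65, 0.96)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 4)
        with pytest.raises(ValueError):
            proportion_ci(-1, 4)

    def test_wilson_option_is_narrower(self):
        cp = proportion_ci(22, 26)
        w = proportion_ci(22, 26, method="wilson")
        assert (w.ci_high - w.ci_low) < (cp.ci_high - cp.ci_low)

    @pytest.mark.parametrize("p", [0.05, 0.5, 0.85])
    def test_coverage_at_least_nominal(self, p):
        """Exact coverage of the n=26 interval is >= 95% (enumerating the
        binomial distribution rather than simulating it)."""
        n = 26
        cover = 0.0
        for k in range(n + 1):
            est = proportion_ci(k, n)
            if est.ci_low <= p <= est.ci_high:
                cover += stats.binom.pmf(k, n, p)
        assert cover >= 0.95


class TestPredictiveValues:
    def test_perfect_test(self):
        assert predictive_values(1, 1, 0.5) == (1, 1)

    @pytest.mark.parametrize("sens, spec, prev, ppv2", [
        (0.85, 0.81, 0.026, 0.11),  # composite score vs DTI
        (0.75, 0.82, 0.051, 0.18),  # composite score vs DL
    ])
    def test_bayes_ppv_at_study_prevalences(self, sens, spec, prev, ppv2):
        ppv, _ = predictive_values(sens, spec, prev)
        assert round(ppv, 2) == ppv2

    def test_undefined_denominator_flagged_as_nan(self):
        ppv, npv = predictive_values(0.0, 1.0, 0.5)
        assert np.isnan(ppv) and npv == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.5, 0.5)


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        curve = empirical_roc([1, 0], [True, False])
        assert np.allclose(curve.fpr, [0, 0, 1])
        assert np.allclose(curve.tpr, [0, 1, 1])
        assert curve.auc() == 1.0

    def test_constant_scores_give_diagonal(self):
        curve = empirical_roc([2, 2, 2, 2], [True, False, True, False])
        assert np.allclose(curve.fpr, [0, 1])
        assert np.allclose(curve.tpr, [0, 1])
        assert curve.auc() == pytest.approx(0.5)

    def test_curve_is_monotone_with_endpoints(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 4, 500).astype(float)
        y = rng.random(500) < 0.3
        curve = empirical_roc(s, y)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_four_level_score_gives_five_points(self):
        out = sample_indicators(DTI_CASE_RATES, 0.0, 2000, rng=1).sum(axis=1)
        ctl = sample_indicators(DTI_CONTROL_RATES, 0.0, 2000, rng=2).sum(axis=1)
        s = np.r_[out, ctl].astype(float)
        y = np.r_[np.ones(2000, bool), np.zeros(2000, bool)]
        curve = empirical_roc(s, y)
        assert curve.tpr.size == 5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            empirical_roc([1.0, 2.0], [True, True])


class TestMannWhitneyAuc:
    def test_binary_predictor_closed_form(self):
        """For a 0/1 predictor, AUC = (sensitivity + specificity) / 2."""
        rng = np.random.default_rng(3)
        y = rng.random(400) < 0.25
        pred = np.where(y, rng.random(400) < 0.8, rng.random(400) < 0.3)
        sens = pred[y].mean()
        spec = 1 - pred[~y].mean()
        assert auc_mann_whitney(pred.astype(float), y) == pytest.approx((sens + spec) / 2)

    def test_complete_separation(self):
        s = np.r_[np.full(5, 2.0), np.full(5, 1.0)]
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        assert auc_mann_whitney(s, y) == 1.0

    def test_equals_trapezoidal_area(self):
        """Rank-based AUC and the trapezoidal area under the tie-aware ROC
        agree to machine precision on random small cohorts."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(4, 31)
            s = rng.integers(0, 5, n).astype(float)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            assert abs(auc_mann_whitney(s, y) - empirical_roc(s, y).auc()) < 1e-12

    def test_matches_reference_implementation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        s = rng.normal(size=300) + rng.random(300)
        y = rng.random(300) < 0.4
        assert auc_mann_whitney(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=200)
        y = rng.random(200) < 0.3
        assert auc_mann_whitney(np.exp(s), y) == pytest.approx(auc_mann_whitney(s, y))


class TestDeLong:
    def test_point_estimate_matches_mann_whitney(self):
        rng = np.random.default_rng(7)
        s = rng.integers(0, 4, 500).astype(float)
        y = rng.random(500) < 0.2
        assert delong_auc(s, y).auc == pytest.approx(auc_mann_whitney(s, y), abs=1e-12)

    def test_identical_scores_compared(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=100)
        y = rng.random(100) < 0.5
        cmp = delong_paired(s, s, y)
        assert cmp.difference == 0.0 and cmp.p_value == 1.0

    def test_monotone_transform_gives_zero_difference(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=100)
        y = rng.random(100) < 0.5
        cmp = delong_paired(s, 3 * s + 2, y)
        assert cmp.auc_a == cmp.auc_b and cmp.difference == 0.0
        assert cmp.p_value == 1.0

    def test_degenerate_scores_flagged_not_raised(self):
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        est = delong_auc(np.ones(10), y)
        assert est.degenerate and est.auc == 0.5

    def test_se_close_to_bootstrap(self):
        """DeLong's analytic SE tracks a 2000-replicate bootstrap SE within
        15% relative error on a fixed simulated cohort (n=300, 60 cases)."""
        rng = np.random.default_rng(10)
        n, n1 = 300, 60
        y = np.r_[np.ones(n1, bool), np.zeros(n - n1, bool)]
        s = rng.normal(size=n) + y
        analytic = delong_auc(s, y).se
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.all() or not yy.any():
                continue
            boot.append(auc_mann_whitney(s[idx], yy))
        assert abs(analytic - np.std(boot, ddof=1)) / np.std(boot, ddof=1) < 0.15

    def test_power_against_weaker_paired_predictor(self):
        """On calibrated synthetic cohorts the composite score beats the
        Mallampati grade often enough that the paired test rejects far more
        often than its nominal 5% level."""
        from airwayus import AirwayStudy, default_config, generate_cohort

        rejections = 0
        n_rep = 150
        for seed in range(n_rep):
            cfg = default_config("DTI", exact_counts=True, seed=1000 + seed)
            study = AirwayStudy.from_records(generate_cohort(cfg))
            cmp = delong_paired(study._oriented("score"),
                                study._oriented("mallampati"), study.labels)
            rejections += cmp.p_value < 0.05
        assert rejections / n_rep > 0.5


class TestYouden:
    def test_perfect_separation(self):
        s = np.r_[np.full(5, 3.0), np.zeros(5)]
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        t, j = youden_optimal(s, y)
        assert j == pytest.approx(1.0)
        assert 0 <= t < 3

    def test_constant_scores(self):
        t, j = youden_optimal(np.ones(10), np.r_[np.ones(5, bool), np.zeros(5, bool)])
        assert j == 0.0

    def test_pmf_enumeration_selects_greater_than_one(self):
        """Under the DTI calibration the optimal rule is 'score > 1', with
        J = 0.36 / 0.70 / 0.47 at thresholds 0 / 1 / 2."""
        case = score_pmf(DTI_CASE_RATES)
        ctrl = score_pmf(DTI_CONTROL_RATES)
        t, j = youden_from_pmfs(case, ctrl)
        assert t == 1
        assert j == pytest.approx(0.696628, abs=1e-6)
        js = [case.sensitivity_above(k) + ctrl.specificity_at_or_below(k) - 1
              for k in (0, 1, 2)]
        assert np.round(js, 2).tolist() == [0.36, 0.70, 0.47]

    def test_sampled_cohort_agrees_with_enumeration(self):
        cases = sample_indicators(DTI_CASE_RATES, 0.0, 20000, rng=11).sum(axis=1)
        ctrls = sample_indicators(DTI_CONTROL_RATES, 0.0, 20000, rng=12).sum(axis=1)
        s = np.r_[cases, ctrls].astype(float)
        y = np.r_[np.ones(20000, bool), np.zeros(20000, bool)]
        t, _ = youden_optimal(s, y)
        assert t == 1.0


class TestScorePmf:
    def test_degenerate(self):
        assert score_pmf((1, 1, 1)).probabilities[3] == 1.0

    def test_symmetric(self):
        assert np.allclose(score_pmf((0.5, 0.5, 0.5)).probabilities,
                           [0.125, 0.375, 0.375, 0.125])

    def test_mean_is_sum_of_rates(self):
        assert score_pmf(DTI_CASE_RATES).mean() == pytest.approx(2.36)
        assert score_pmf(DTI_CONTROL_RATES).mean() == pytest.approx(0.84)

    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            ScorePmf(np.array([0.5, 0.5, 0.5, 0.5]))

    def test_correlated_pmf_reduces_to_independent_at_zero(self):
        a = score_pmf_correlated(DTI_CASE_RATES, 0.0)
        b = score_pmf(DTI_CASE_RATES)
        assert np.allclose(a.probabilities, b.probabilities)

    @pytest.mark.parametrize("rho", [0.2, 0.5])
    def test_correlation_preserves_the_mean(self, rho):
        """The copula changes co-occurrence, never the marginals, so the
        expected score is invariant in rho."""
        assert score_pmf_correlated(DTI_CASE_RATES, rho).mean() == pytest.approx(2.36, abs=1e-9)

    def test_correlated_pmf_matches_simulation(self):
        n = 100_000
        sums = sample_indicators(DTI_CONTROL_RATES, 0.3, n, rng=13).sum(axis=1)
        sim = np.bincount(sums, minlength=4) / n
        exact = score_pmf_correlated(DTI_CONTROL_RATES, 0.3).probabilities
        se = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(sim - exact) < 4 * se + 1e-9)


class TestPmfAuc:
    def test_identical_pmfs(self):
        p = score_pmf((0.4, 0.5, 0.6))
        assert pmf_auc(p, p) == pytest.approx(0.5)

    def test_complete_separation(self):
        hi = ScorePmf(np.array([0, 0, 0, 1.0]))
        lo = ScorePmf(np.array([1.0, 0, 0, 0]))
        assert pmf_auc(hi, lo) == 1.0

    def test_dti_calibration_value(self):
        auc = pmf_auc(score_pmf(DTI_CASE_RATES), score_pmf(DTI_CONTROL_RATES))
        assert auc == pytest.approx(0.9025, abs=5e-4)

    def test_agrees_with_simulated_auc_under_independence(self):
        n = 100_000
        cases = sample_indicators(DTI_CASE_RATES, 0.0, n, rng=14).sum(axis=1)
        ctrls = sample_indicators(DTI_CONTROL_RATES, 0.0, n, rng=15).sum(axis=1)
        s = np.r_[cases, ctrls].astype(float)
        y = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        est = delong_auc(s, y)
        exact = pmf_auc(score_pmf(DTI_CASE_RATES), score_pmf(DTI_CONTROL_RATES))
        assert abs(est.auc - exact) < 3 * est.se
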