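"""ROC/AUC, bootstrap, predictive values and demographic-table statistics
against exhaustive pair-counting, hypergeometric enumeration and the Bayes
PPV closed form."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptbpanel import performance_eval as pe
from ptbpanel import risk_scoring as rs


def auc_pair_counting(scores, y):
    """Oracle: exhaustive case/control pair comparison."""
    scores = np.asarray(scores, float)
    cases = scores[np.asarray(y) == 1]
    ctrls = scores[np.asarray(y) == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
    return wins / (len(cases) * len(ctrls))


def auc_trapezoid(scores, y):
    """Oracle: trapezoidal area under the empirical ROC curve."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = [(scores[y == 1] >= t).mean() for t in thresholds] + [1.0]
    fpr = [(scores[y == 0] >= t).mean() for t in thresholds] + [1.0]
    return float(np.trapezoid(tpr, fpr))


class TestAuc:
    def test_interleaved_example(self):
        assert pe.auc_mann_whitney([1, 3, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert pe.auc_mann_whitney([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_all_ties_half(self):
        assert pe.auc_mann_whitney([5, 5, 5, 5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pe.auc_mann_whitney([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 500))
        scores = rng.integers(0, 15, size=n).astype(float)  # heavy ties
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        assert pe.auc_mann_whitney(scores, y) == pytest.approx(
            auc_pair_counting(scores, y), abs=1e-12
        )

    def test_matches_trapezoidal_roc_area(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=300).round(1)
        y = rng.integers(0, 2, size=300)
        y[:2] = [0, 1]
        assert pe.auc_mann_whitney(scores, y) == pytest.approx(
            auc_trapezoid(scores, y), abs=1e-12
        )


class TestBootstrapCI:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        a = pe.bootstrap_ci(scores, y, n_reps=200, seed=5)
        b = pe.bootstrap_ci(scores, y, n_reps=200, seed=5)
        assert a == b

    def test_constant_metric_collapses(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        y = [0, 0, 1, 1]
        lo, hi = pe.bootstrap_ci(scores, y, metric=lambda s, yy: 0.42, n_reps=50, seed=0)
        assert lo == hi == pytest.approx(0.42)

    def test_coverage_under_binormal_model(self):
        # true AUC 0.80 at n=200/200; the percentile 95% CI should cover the
        # truth in about 95% of outer replications
        delta = np.sqrt(2) * stats.norm.ppf(0.80)
        rng = np.random.default_rng(123)
        outer = 200
        covered = 0
        y = np.array([0] * 200 + [1] * 200)
        for _ in range(outer):
            scores = np.concatenate(
                [rng.normal(0, 1, 200), rng.normal(delta, 1, 200)]
            )
            lo, hi = pe.bootstrap_ci(
                scores, y, n_reps=1000, seed=int(rng.integers(2**31))
            )
            covered += lo <= 0.80 <= hi
        assert covered / outer == pytest.approx(0.95, abs=0.03)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        cm = pe.confusion_metrics(["high", "high", "low"], [1, 1, 0])
        assert (cm.sensitivity, cm.specificity, cm.ppv, cm.npv) == (1, 1, 1, 1)

    def test_all_predicted_low_flags_undefined_ppv(self):
        cm = pe.confusion_metrics(["low", "low"], [1, 0])
        assert cm.sensitivity == 0 and cm.specificity == 1
        assert not cm.ppv_defined and np.isnan(cm.ppv)

    def test_two_by_two_arithmetic(self):
        pred = ["high"] * 8 + ["low"] * 2 + ["high"] * 9 + ["low"] * 81
        y = [1] * 10 + [0] * 90
        cm = pe.confusion_metrics(pred, y)
        assert cm.sensitivity == pytest.approx(0.8)
        assert cm.specificity == pytest.approx(0.9)
        assert cm.ppv == pytest.approx(8 / 17, abs=5e-4)
        assert cm.npv == pytest.approx(81 / 83, abs=5e-4)


class TestStratification:
    def test_trimester_boundaries_completed_weeks(self):
        # 13.9 wk is 13 weeks + 6.3 days -> still T1; 14.0 starts T2; 28 starts T3
        assert pe.trimester(13.9) == "T1"
        assert pe.trimester(14.0) == "T2"
        assert pe.trimester(27.9) == "T2"
        assert pe.trimester(28.0) == "T3"

    def test_ga_bins(self):
        assert pe.ga_bin(15.9) == "<16"
        assert pe.ga_bin(16.0) == "16-20"
        assert pe.ga_bin(20.9) == "16-20"  # 20 weeks + 6 days inclusive
        assert pe.ga_bin(21.0) == ">20"

    def _table(self, n, ga=18.0):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            dict(
                ga_sample_wk=[ga] * n,
                group=["sptb" if i % 2 else "term" for i in range(n)],
                score=rng.normal(size=n),
            )
        )

    def test_small_stratum_suppressed(self):
        model = rs.ThresholdModel("three_protein", 0.0, "uab", 0.2)
        scheme = pe.StratificationScheme("none", min_stratum_n=15)
        out = pe.stratified_performance(
            self._table(14), "score", scheme, model, bootstrap_reps=20
        )
        assert out.iloc[0]["suppressed"]
        assert "insufficient n" in out.iloc[0]["reason"]

    def test_scheme_none_single_stratum(self):
        model = rs.ThresholdModel("three_protein", 0.0, "uab", 0.2)
        scheme = pe.StratificationScheme("none", min_stratum_n=15)
        out = pe.stratified_performance(
            self._table(30), "score", scheme, model, bootstrap_reps=20
        )
        assert len(out) == 1 and out.iloc[0]["stratum"] == "all"
        assert not out.iloc[0]["suppressed"]


class TestPrevalenceBootstrap:
    def _classifier(self, sens, spec, n_case=200, n_ctrl=200, seed=0):
        """Scores such that threshold 0 gives the requested sens/spec."""
        rng = np.random.default_rng(seed)
        case = np.where(rng.random(n_case) < sens, 1.0, -1.0)
        ctrl = np.where(rng.random(n_ctrl) < spec, -1.0, 1.0)
        scores = np.concatenate([case, ctrl])
        y = np.array([1] * n_case + [0] * n_ctrl)
        return scores, y

    def test_perfect_classifier_ppv_one(self):
        scores = np.array([1.0] * 20 + [-1.0] * 20)
        y = np.array([1] * 20 + [0] * 20)
        model = rs.ThresholdModel("three_protein", 0.0, "uab", 1.0)
        out = pe.prevalence_weighted_bootstrap(
            scores, y, model, pe.PrevalenceBootstrapConfig(0.104, n_reps=100, seed=0)
        )
        assert out["ppv"]["mean"] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "prevalence,expected",
        [(0.104, 0.4815), (0.059, 0.334)],  # Bayes: se*pi / (se*pi + (1-sp)(1-pi))
    )
    def test_bayes_oracle(self, prevalence, expected):
        scores, y = self._classifier(0.8, 0.9, 2000, 2000)
        model = rs.ThresholdModel("three_protein", 0.0, "uab", 0.7)
        out = pe.prevalence_weighted_bootstrap(
            scores, y, model,
            pe.PrevalenceBootstrapConfig(prevalence, n_reps=1000, seed=1),
        )
        reps = out["ppv_replicates"]
        se = np.nanstd(reps) / np.sqrt(np.isfinite(reps).sum())
        # allow for the empirical sens/spec of the finite analytic set
        emp_sens = (scores[y == 1] >= 0).mean()
        emp_spec = (scores[y == 0] < 0).mean()
        bayes = emp_sens * prevalence / (
            emp_sens * prevalence + (1 - emp_spec) * (1 - prevalence)
        )
        assert abs(out["ppv"]["mean"] - bayes) < 3 * max(se, 1e-4)
        assert out["ppv"]["mean"] == pytest.approx(expected, abs=0.03)

    def test_deterministic_given_seed(self):
        scores, y = self._classifier(0.7, 0.8, 50, 50)
        model = rs.ThresholdModel("three_protein", 0.0, "uab", 0.5)
        cfg = pe.PrevalenceBootstrapConfig(0.104, n_reps=50, seed=9)
        a = pe.prevalence_weighted_bootstrap(scores, y, model, cfg)
        b = pe.prevalence_weighted_bootstrap(scores, y, model, cfg)
        assert a["ppv"]["mean"] == b["ppv"]["mean"]

    def test_too_small_for_prevalence_rejected(self):
        scores, y = self._classifier(0.8, 0.9, 3, 3)
        model = rs.ThresholdModel("three_protein", 0.0, "uab", 0.5)
        with pytest.raises(ValueError, match="larger"):
            pe.prevalence_weighted_bootstrap(
                scores, y, model, pe.PrevalenceBootstrapConfig(0.05, n_reps=10, seed=0)
            )


class TestCrossPlatform:
    def test_identical_vectors(self):
        out = pe.cross_platform_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["bias"] == 0 and out["loa_low"] == out["loa_high"] == 0

    def test_hand_correlation(self):
        out = pe.cross_platform_agreement([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert out["pearson_r"] == pytest.approx(0.5)

    def test_constant_shift(self):
        a = np.array([1.0, 2.0, 3.0])
        out = pe.cross_platform_agreement(a, a + 1)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["bias"] == pytest.approx(-1.0)
        assert out["loa_low"] == pytest.approx(-1.0)
        assert out["loa_high"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        out = pe.cross_platform_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not out["r_defined"] and np.isnan(out["pearson_r"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pe.cross_platform_agreement([1.0, 2.0], [1.0, 2.0])


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestDemographicStats:
    def test_pooled_t_from_printed_summaries(self):
        t, df, p = pe.pooled_t_from_summary(11, 25.5, 5.1, 14, 26.9, 4.7)
        assert df == 23
        assert round(abs(t), 1) == 0.7
        assert p == pytest.approx(0.49, abs=0.01)

    def test_fisher_exact_printed_table(self):
        # delivery-mode 2x2 of the discovery cohort: cesarean 0 vs 6, vaginal 11 vs 7
        assert pe.fisher_exact_2x2([[0, 6], [11, 7]]) == pytest.approx(0.016, abs=5e-4)

    def test_fisher_identical_rows_p_one(self):
        assert pe.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[1, 9], [9, 1]], [[0, 6], [11, 7]], [[3, 7], [12, 2]], [[10, 5], [4, 11]]],
    )
    def test_fisher_matches_enumeration(self, table):
        assert pe.fisher_exact_2x2(table) == pytest.approx(
            fisher_enumeration_oracle(table), rel=1e-9
        )

    def test_fisher_rejects_noninteger(self):
        with pytest.raises(ValueError):
            pe.fisher_exact_2x2([[0.5, 1], [2, 3]])

    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[14, 17], [25, 6]], 8.36),
            ([[61, 67], [133, 47]], 22.08),
        ],
    )
    def test_chi_square_printed_tables(self, table, expected):
        chi2, dof, _ = pe.chi_square_2xk(table)
        assert chi2 == pytest.approx(expected, abs=5e-3)
        assert dof == 1

    @pytest.mark.parametrize("n1,n2", [(19, 31), (50, 23), (7, 13)])
    def test_chi_square_separated_equals_n(self, n1, n2):
        chi2, _, _ = pe.chi_square_2xk([[n1, 0], [0, n2]])
        assert chi2 == pytest.approx(n1 + n2)

    def test_cohort_table_stats_end_to_end(self):
        rng = np.random.default_rng(4)
        n = 60
        frame = pd.DataFrame(
            dict(
                group=["term"] * 30 + ["sptb"] * 30,
                age_yr=rng.normal(30, 4, n),
                bmi=rng.normal(24, 3, n),
                mode_delivery=rng.choice(["cesarean", "nsvd"], n),
            )
        )
        out = pe.cohort_table_stats(frame)
        assert set(out["variable"]) == {"age_yr", "bmi", "mode_delivery"}
        assert (out["p"].between(0, 1)).all()

    def test_sparse_categorical_uses_fisher(self):
        frame = pd.DataFrame(
            dict(
                group=["term"] * 11 + ["sptb"] * 14,
                age_yr=np.r_[np.random.default_rng(0).normal(30, 4, 25)],
                bmi=np.r_[np.random.default_rng(1).normal(24, 3, 25)],
                mode_delivery=["nsvd"] * 11 + ["cesarean"] * 6 + ["nsvd"] * 8,
            )
        )
        out = pe.cohort_table_stats(frame)
        row = out[out["variable"] == "mode_delivery"].iloc[0]
        assert row["test"] == "Fisher exact"
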