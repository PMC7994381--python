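import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from nbscreen import survival
from nbscreen.io_formats import CLINICAL_COLUMNS


def make_clinical(times, events, index=None, **covariates):
    n = len(times)
    index = index if index is not None else [f"s{i}" for i in range(n)]
    base = {
        "os_time": times,
        "os_event": events,
        "efs_time": times,
        "efs_event": events,
        "stage_advanced": np.zeros(n, dtype=int),
        "age_over_18m": np.zeros(n, dtype=int),
        "mycn_amplified": np.zeros(n, dtype=int),
    }
    base.update(covariates)
    return pd.DataFrame(base, index=pd.Index(index, name="sample"))[CLINICAL_COLUMNS]


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = survival.km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_single_death_among_four(self):
        km = survival.km_estimate([5.0, 9.0, 10.0, 11.0], [1, 0, 0, 0])
        assert km.survival_at(5.0) == pytest.approx(0.75)

    def test_hand_product_limit(self):
        km = survival.km_estimate([2.0, 4.0, 6.0, 8.0], [1, 1, 0, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.0])
        assert km.at_risk.tolist() == [4, 3, 1]

    def test_no_censoring_equals_empirical_fraction(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(100.0, size=50)
        km = survival.km_estimate(t, np.ones(50, dtype=int))
        for tau, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((t > tau).mean(), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            survival.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [2.0, 4.0, 6.0, 2.0, 4.0, 6.0]
        e = [1, 1, 0, 1, 1, 0]
        stat, p = survival.logrank_test(t, e, [0, 0, 0, 1, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        t = [2.0, 5.0, 9.0, 4.0, 7.0, 11.0]
        e = [1, 0, 1, 1, 1, 1]
        g = np.array([0, 0, 0, 1, 1, 1])
        stat_a, p_a = survival.logrank_test(t, e, g)
        stat_b, p_b = survival.logrank_test(t, e, 1 - g)
        assert stat_a == pytest.approx(stat_b, abs=1e-12)
        assert p_a == pytest.approx(p_b, abs=1e-12)

    def test_hand_worked_six_subject_fixture(self):
        # exact tabulation over event times gives O-E = -4/15, Var = 433/450,
        # so the chi-squared statistic is (4/15)^2 / (433/450) = 32/433
        stat, p = survival.logrank_test(
            [2.0, 5.0, 9.0, 4.0, 7.0, 11.0], [1, 0, 1, 1, 1, 1], [0, 0, 0, 1, 1, 1]
        )
        assert stat == pytest.approx(32 / 433, abs=1e-10)

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(4)
        g = (rng.random(80) < 0.5).astype(int)
        t = rng.exponential(100 * (1 + g))
        e = (rng.random(80) < 0.8).astype(int)
        stat, p = survival.logrank_test(t, e, g)
        ref = lifelines_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert stat == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-12)

    def test_matches_cox_score_test_without_ties(self):
        rng = np.random.default_rng(5)
        g = np.r_[np.zeros(30), np.ones(30)].astype(int)
        t = rng.exponential(100.0, size=60)  # continuous: no ties
        e = np.ones(60, dtype=int)
        stat, p = survival.logrank_test(t, e, g)
        fit = survival.cox_fit(g[:, None].astype(float), t, e)
        assert p == pytest.approx(fit.score_p, rel=1e-2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            survival.logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestCoxFit:
    def test_agrees_with_lifelines_two_covariates(self):
        rng = np.random.default_rng(3)
        n = 120
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = rng.normal(size=n)
        t_lat = rng.exponential(1 / (0.002 * np.exp(0.7 * x1 - 0.3 * x2)))
        cens = rng.uniform(0, 1200, n)
        t, e = np.minimum(t_lat, cens), (t_lat <= cens).astype(int)
        fit = survival.cox_fit(np.column_stack([x1, x2]), t, e)
        ref = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2}), "t", "e"
        )
        assert np.allclose(fit.beta, ref.params_[["x1", "x2"]], atol=1e-6)
        assert np.allclose(fit.se, ref.standard_errors_[["x1", "x2"]], atol=1e-6)
        assert fit.converged

    def test_null_covariate_within_three_se(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(100.0, size=n)
        e = np.ones(n, dtype=int)
        fit = survival.cox_fit(x[:, None], t, e)
        assert abs(fit.beta[0]) < 3 * fit.se[0]

    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(7)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.001 * np.exp(np.log(2.0) * x)))
        fit = survival.cox_fit(x[:, None], t, np.ones(n, dtype=int))
        assert 1.7 < fit.hr[0] < 2.35

    def test_time_rescaling_leaves_beta_unchanged(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(50.0, size=n)
        e = (rng.random(n) < 0.7).astype(int)
        f1 = survival.cox_fit(x[:, None], t, e)
        f2 = survival.cox_fit(x[:, None], 1000.0 * t, e)
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            survival.cox_fit(np.ones((10, 1)), np.arange(1.0, 11.0), np.ones(10, int))

    def test_separation_flagged_not_crashed(self):
        # group 0 all fails early, group 1 all censored late: monotone likelihood
        t = np.r_[np.arange(1.0, 6.0), np.arange(100.0, 105.0)]
        e = np.r_[np.ones(5), np.zeros(5)].astype(int)
        x = np.r_[np.ones(5), np.zeros(5)].astype(float)
        fit = survival.cox_fit(x[:, None], t, e)
        assert not fit.converged


class TestDichotomize:
    def test_even_split(self):
        labels = survival.dichotomize_by_median([1.0, 2.0, 3.0, 4.0])
        assert labels.tolist() == [0, 0, 1, 1]

    def test_median_value_goes_low_for_odd_n(self):
        assert survival.dichotomize_by_median([1.0, 2.0, 3.0]).tolist() == [0, 0, 1]

    def test_all_equal_all_low(self):
        assert survival.dichotomize_by_median([2.0, 2.0, 2.0, 2.0]).sum() == 0


class TestSurvivalFilter:
    @staticmethod
    def cohort(hr, n=300, seed=0):
        rng = np.random.default_rng(seed)
        expr_v = rng.normal(size=n)
        high = (expr_v > np.median(expr_v)).astype(int)
        t_lat = rng.exponential(1 / (0.001 * np.exp(np.log(hr) * high)))
        cens = rng.uniform(0, 3000, n)
        t, e = np.maximum(np.minimum(t_lat, cens), 1e-6), (t_lat <= cens).astype(int)
        expr = pd.DataFrame(
            expr_v[None, :],
            index=pd.Index(["gene"], name="gene_id"),
            columns=[f"s{i}" for i in range(n)],
        )
        return expr, make_clinical(t, e, index=expr.columns)

    def test_risk_gene_passes(self):
        expr, clin = self.cohort(hr=2.5)
        res = survival.survival_filter(expr, clin)
        assert res.loc["gene", "passes"] and res.loc["gene", "hr"] > 1

    def test_protective_gene_fails_despite_small_p(self):
        expr, clin = self.cohort(hr=0.4)
        res = survival.survival_filter(expr, clin)
        assert res.loc["gene", "logrank_p"] < 0.05
        assert res.loc["gene", "hr"] < 1 and not res.loc["gene", "passes"]

    def test_constant_expression_skipped_with_warning(self):
        expr, clin = self.cohort(hr=2.0)
        expr.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant expression"):
            res = survival.survival_filter(expr, clin)
        assert not res.loc["flat", "passes"] and np.isnan(res.loc["flat", "hr"])

    def test_misaligned_samples_rejected(self):
        expr, clin = self.cohort(hr=2.0)
        with pytest.raises(ValueError, match="missing from clinical"):
            survival.survival_filter(expr.rename(columns={"s0": "zz"}), clin)


class TestMultivariateCox:
    @staticmethod
    def simulated(seed=0, n=400, mediated=False):
        rng = np.random.default_rng(seed)
        label = (rng.random(n) < 0.5).astype(int)
        if mediated:
            covariate = np.where(rng.random(n) < 0.9, label, 1 - label)
        else:
            covariate = (rng.random(n) < 0.5).astype(int)
        hazard = 0.001 * np.exp(np.log(2.5) * (covariate if mediated else label))
        t_lat = rng.exponential(1 / hazard)
        cens = rng.uniform(0, 3000, n)
        t, e = np.minimum(t_lat, cens), (t_lat <= cens).astype(int)
        clin = make_clinical(
            np.maximum(t, 1e-6), e, index=[f"s{i}" for i in range(n)],
            stage_advanced=covariate,
            age_over_18m=(rng.random(n) < 0.5).astype(int),
            mycn_amplified=(rng.random(n) < 0.3).astype(int),
        )
        return label, clin

    def test_independent_covariates_leave_hr_close_to_univariate(self):
        label, clin = self.simulated(seed=1)
        uni = survival.multivariate_cox(label, clin, covariates=())
        multi = survival.multivariate_cox(label, clin, covariates=("stage_advanced",))
        assert multi.hr[0] == pytest.approx(uni.hr[0], rel=0.15)

    def test_mediated_effect_attenuates_towards_one(self):
        label, clin = self.simulated(seed=2, mediated=True)
        uni = survival.multivariate_cox(label, clin, covariates=())
        multi = survival.multivariate_cox(label, clin, covariates=("stage_advanced",))
        assert multi.hr[0] < uni.hr[0]
        assert abs(np.log(multi.hr[0])) < 0.5 * abs(np.log(uni.hr[0]))

    def test_empty_covariates_reduce_to_univariate(self):
        label, clin = self.simulated(seed=3)
        uni = survival.cox_fit(
            np.asarray(label, float)[:, None],
            clin["os_time"].to_numpy(),
            clin["os_event"].to_numpy(),
        )
        multi = survival.multivariate_cox(label, clin, covariates=())
        assert np.allclose(multi.beta, uni.beta, atol=1e-10)


class TestAdditiveAttenuation:
    def test_one_row_per_covariate(self):
        label, clin = TestMultivariateCox.simulated(seed=4)
        table = survival.additive_cox_attenuation(label, clin)
        assert sorted(table["covariate"]) == sorted(survival.PROGNOSTIC_COVARIATES)

    def test_planted_confounder_ranks_first(self):
        label, clin = TestMultivariateCox.simulated(seed=5, mediated=True)
        table = survival.additive_cox_attenuation(label, clin)
        assert table.iloc[0]["covariate"] == "stage_advanced"

    def test_null_covariates_barely_move_hr(self):
        label, clin = TestMultivariateCox.simulated(seed=6)
        table = survival.additive_cox_attenuation(label, clin)
        assert (table["delta_hr"].abs() < 0.25).all()
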