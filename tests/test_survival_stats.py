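"""KM/log-rank/Cox machinery, model selection, combined strata, power formula."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from aneuscore import (
    SimulationConfig,
    backward_selection,
    combined_strata_fit,
    cox_fit,
    km_estimate,
    logrank_test,
    required_events,
    simulate_cohort,
    univariate_screen,
)
from aneuscore.survival_stats import add_dichotomized, univariate_table


def make_df(times, events, **covs):
    return pd.DataFrame({"os_months": times, "event": events, **covs})


# Tie-free 6-patient fixture with a binary covariate.
TIMES6 = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
EVENTS6 = [1, 1, 0, 1, 1, 1]
X6 = [1, 0, 1, 0, 1, 0]  # interleaved with event times so the MLE is finite


def negloglik_no_ties(beta, times, events, x):
    """Hand-coded Cox partial likelihood for tie-free data (oracle)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return -ll


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        surv = dict(zip(km.times, km.survival))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_all_censored(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert np.allclose(km.survival, 1.0)
        assert math.isnan(km.median)

    def test_hand_computed_product_limit(self):
        """6 patients, censoring at t=2 and t=5 reduces the risk set only."""
        km = km_estimate(TIMES6, [1, 0, 1, 1, 0, 1])
        surv = dict(zip(km.times, km.survival))
        assert surv[1.0] == pytest.approx(5 / 6)
        assert surv[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert surv[4.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert surv[6.0] == pytest.approx(0.0)
        assert km.median == pytest.approx(4.0)  # earliest t with S <= 0.5

    def test_no_censoring_matches_empirical(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        km = km_estimate(t, np.ones(40))
        for ti, si in zip(km.times[1:], km.survival[1:]):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_null(self):
        t, e = TIMES6, [1, 1, 1, 1, 1, 1]
        res = logrank_test(t + t, e + e, [0] * 6 + [1] * 6)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_separated_groups(self):
        early = list(range(1, 11))
        late = list(range(100, 110))
        res = logrank_test(early + late, [1] * 20, [0] * 10 + [1] * 10)
        assert res.p < 0.01

    def test_three_groups_df(self):
        rng = np.random.default_rng(1)
        res = logrank_test(rng.exponential(5, 30), np.ones(30), [0, 1, 2] * 10)
        assert res.df == 2

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])


class TestCoxFit:
    def test_brute_force_oracle(self):
        """Beta matches direct maximization of the hand-coded partial likelihood."""
        df = make_df(TIMES6, EVENTS6, x=X6)
        opt = optimize.minimize_scalar(
            negloglik_no_ties, bounds=(-10, 10), method="bounded",
            args=(TIMES6, EVENTS6, X6), options={"xatol": 1e-10},
        )
        for ties in ("efron", "breslow"):
            fit = cox_fit(df, ["x"], ties=ties)
            assert fit.term("x").coef == pytest.approx(opt.x, abs=1e-4)

    def test_lifelines_cross_check(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 60).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * x)))
        df = make_df(t, np.ones(60, dtype=int), x=x)
        fit = cox_fit(df, ["x"])
        cph = CoxPHFitter().fit(df, "os_months", "event")
        assert fit.term("x").coef == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.term("x").se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)
        assert fit.aic == pytest.approx(cph.AIC_partial_, abs=1e-6)

    def test_efron_equals_breslow_tie_free(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        df = make_df(t, rng.integers(0, 2, 50), x=x)
        if df["event"].sum() == 0:
            df.loc[0, "event"] = 1
        fe = cox_fit(df, ["x"], ties="efron")
        fb = cox_fit(df, ["x"], ties="breslow")
        assert fe.term("x").coef == pytest.approx(fb.term("x").coef, abs=1e-10)
        assert fe.aic == pytest.approx(fb.aic, abs=1e-8)

    def test_constant_covariate_errors(self):
        df = make_df(TIMES6, EVENTS6, x=[1] * 6)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_no_events_errors(self):
        df = make_df(TIMES6, [0] * 6, x=X6)
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["x"])

    def test_missing_values_error(self):
        df = make_df(TIMES6, EVENTS6, x=[1, 0, None, 1, 0, 1])
        with pytest.raises(ValueError, match="missing values"):
            cox_fit(df, ["x"])

    def test_duplication_keeps_hr_shrinks_se(self):
        # exact under Breslow (tied risk-set sums scale out); Efron's within-tie
        # adjustment makes it only approximate
        df = make_df(TIMES6, EVENTS6, x=X6)
        fit1 = cox_fit(df, ["x"], ties="breslow")
        fit2 = cox_fit(pd.concat([df, df], ignore_index=True), ["x"], ties="breslow")
        assert fit2.term("x").hr == pytest.approx(fit1.term("x").hr, rel=1e-6)
        assert fit2.term("x").se < fit1.term("x").se

    def test_flipped_covariate_reciprocal_hr(self):
        df = make_df(TIMES6, EVENTS6, x=X6, xf=[1 - v for v in X6])
        f1 = cox_fit(df, ["x"])
        f2 = cox_fit(df, ["xf"])
        assert f2.term("xf").hr == pytest.approx(1 / f1.term("x").hr, rel=1e-6)

    def test_time_rescaling_invariance(self):
        df1 = make_df(TIMES6, EVENTS6, x=X6)
        df2 = make_df([t * 12 for t in TIMES6], EVENTS6, x=X6)
        assert cox_fit(df1, ["x"]).term("x").coef == pytest.approx(
            cox_fit(df2, ["x"]).term("x").coef, abs=1e-8
        )

    def test_ci_brackets_hr(self):
        fit = cox_fit(make_df(TIMES6, EVENTS6, x=X6), ["x"])
        t = fit.term("x")
        assert t.ci_low < t.hr < t.ci_high and t.hr > 0


@pytest.fixture(scope="module")
def sim_clinical(hg19_arms):
    cfg = SimulationConfig(n_patients=400, seed=31)
    clin = simulate_cohort(cfg, hg19_arms).clinical
    clin = add_dichotomized(clin)
    clin["aneuploid"] = clin["aneuploid_true"].astype(int)
    return clin


class TestSelection:
    def test_empty_candidates(self, sim_clinical):
        assert univariate_screen(sim_clinical, []) == []

    def test_strong_covariate_retained(self, sim_clinical):
        retained = univariate_screen(sim_clinical, ["aneuploid", "ctc_high"])
        assert set(retained) == {"aneuploid", "ctc_high"}

    def test_backward_keeps_only_signal(self, sim_clinical):
        df = sim_clinical.copy()
        rng = np.random.default_rng(8)
        df["noise"] = rng.normal(size=len(df))
        fit = backward_selection(df, ["aneuploid", "noise"])
        assert fit.term_names == ["aneuploid"]

    def test_backward_fixed_point(self, sim_clinical):
        fit_full = cox_fit(sim_clinical, ["aneuploid", "ctc_high"])
        fit_sel = backward_selection(sim_clinical, ["aneuploid", "ctc_high"])
        assert fit_sel.term_names == fit_full.term_names
        assert fit_sel.aic == pytest.approx(fit_full.aic)

    def test_backward_deterministic(self, sim_clinical):
        df = sim_clinical.copy()
        rng = np.random.default_rng(9)
        df["n1"] = rng.normal(size=len(df))
        df["n2"] = rng.normal(size=len(df))
        runs = [
            backward_selection(df, ["aneuploid", "n1", "n2"]).term_names
            for _ in range(3)
        ]
        assert runs[0] == runs[1] == runs[2]

    def test_all_removed_returns_empty_model(self):
        rng = np.random.default_rng(10)
        df = make_df(
            rng.exponential(10, 80), np.ones(80, dtype=int), x=rng.normal(size=80)
        )
        fit = backward_selection(df, ["x"], p_drop=1e-9)
        assert fit.terms == []
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood)

    def test_aic_drops_with_prognostic_covariate(self, sim_clinical):
        null = cox_fit(sim_clinical, [])
        with_marker = cox_fit(sim_clinical, ["aneuploid"])
        assert with_marker.aic < null.aic


class TestCombinedStrata:
    def test_additive_hazards_multiply(self, hg19_arms):
        cfg = SimulationConfig(n_patients=1500, seed=23)
        clin = add_dichotomized(simulate_cohort(cfg, hg19_arms).clinical)
        clin["aneuploid"] = clin["aneuploid_true"].astype(int)
        res = combined_strata_fit(clin)
        b_both = res.cox.term("ctc_high_aneuploid").coef
        expected = cfg.log_hr_aneuploidy + cfg.log_hr_ctc
        se = res.cox.term("ctc_high_aneuploid").se
        assert abs(b_both - expected) < 3 * se

    def test_group_labels_and_logrank(self, scored_cohort):
        res = combined_strata_fit(scored_cohort)
        assert res.group_labels.nunique() >= 2
        assert 0 <= res.logrank.p <= 1
        assert set(res.km) == set(res.group_labels.unique())

    def test_single_group_errors(self):
        df = make_df(TIMES6, EVENTS6, aneuploid=[0] * 6, ctc_high=[0] * 6)
        with pytest.raises(ValueError, match="single combined group"):
            combined_strata_fit(df)

    def test_empty_reference_errors(self):
        df = make_df(TIMES6, EVENTS6, aneuploid=[1] * 6, ctc_high=[0, 1] * 3)
        with pytest.raises(ValueError, match="reference group"):
            combined_strata_fit(df)


class TestRequiredEvents:
    def test_direct_evaluation(self):
        assert required_events(2.0, alpha=0.05, power=0.8, p_group=0.5) == 66

    def test_monotone_in_power(self):
        assert required_events(2.0, power=0.5) < required_events(2.0, power=0.8)

    def test_balanced_groups_minimize(self):
        d_half = required_events(2.0, p_group=0.5)
        for p in (0.1, 0.3, 0.7, 0.9):
            assert required_events(2.0, p_group=p) >= d_half

    def test_hr_one_errors(self):
        with pytest.raises(ValueError):
            required_events(1.0)
        with pytest.raises(ValueError):
            required_events(-2.0)
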