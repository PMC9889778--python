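"""Log-rank, maximally selected cutpoints, Cox proportional hazards."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

from fibroscape.survival import (
    apply_horizon,
    cox_ph,
    cutpoint_sweep,
    logrank_statistic,
    logrank_test,
)
from fibroscape.synthetic import SurvivalConfig, generate_survival_cohort


class TestLogrank:
    def test_identical_groups_give_null(self):
        time = np.array([2.0, 4, 6, 8, 2, 4, 6, 8])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_eight_subject_table(self):
        """U and Var match the by-hand hypergeometric tabulation."""
        time = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        group = np.array([1, 0, 1, 1, 0, 1, 0, 0]).astype(bool)
        # hand tabulation: event times 1,2,3,5,6,8
        # t=1: n=8 n1=4 d=1 d1=1 -> U+=1-4/8, V+=(4/8)(4/8)(7/7)
        # t=2: n=7 n1=3 d=1 d1=0 -> U+=-3/7, V+=(3/7)(4/7)
        # t=3: n=6 n1=3 d=1 d1=1 -> U+=1-3/6, V+=(3/6)(3/6)
        # t=5: n=4 n1=1 d=1 d1=0 -> U+=-1/4, V+=(1/4)(3/4)
        # t=6: n=3 n1=1 d=1 d1=1 -> U+=1-1/3, V+=(1/3)(2/3)
        # t=8: n=1 n1=0 d=1 d1=0 -> U+=0,    V+=0
        U_hand = (1 - 0.5) + (-3 / 7) + 0.5 + (-0.25) + (2 / 3) + 0.0
        V_hand = 0.25 + 12 / 49 + 0.25 + 3 / 16 + 2 / 9 + 0.0
        U, V = logrank_statistic(time, event, group)
        assert U == pytest.approx(U_hand, abs=1e-12)
        assert V == pytest.approx(V_hand, abs=1e-12)

    def test_matches_lifelines(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=120, seed=8))
        group = df["score"] > df["score"].median()
        chi2, p = logrank_test(df["time_months"], df["event"], group)
        from lifelines.statistics import logrank_test as ll_logrank

        ll = ll_logrank(
            df.loc[group, "time_months"], df.loc[~group, "time_months"],
            df.loc[group, "event"], df.loc[~group, "event"],
        )
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-6)
        assert p == pytest.approx(ll.p_value, rel=1e-6)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            logrank_test([1.0, 2.0], [0, 0], [0, 1])


class TestCutpointSweep:
    def test_equals_exhaustive_enumeration(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=100, seed=5))
        cp = cutpoint_sweep(df["time_months"], df["event"], df["score"])
        for _, row in cp.table.iterrows():
            U, V = logrank_statistic(
                df["time_months"], df["event"], df["score"] > row["cutpoint"]
            )
            assert row["statistic"] == pytest.approx(U / np.sqrt(V), abs=1e-10)
        best = cp.table.loc[cp.table["statistic"].abs().idxmax()]
        assert cp.optimal_cutpoint == best["cutpoint"]

    def test_statistic_squared_equals_chi2(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=80, seed=6))
        cp = cutpoint_sweep(df["time_months"], df["event"], df["score"])
        chi2, _ = logrank_test(
            df["time_months"], df["event"], df["score"] > cp.optimal_cutpoint
        )
        assert chi2 == pytest.approx(cp.optimal_statistic**2, rel=1e-10)

    def test_invariant_to_monotone_score_transform(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=90, seed=7))
        cp1 = cutpoint_sweep(df["time_months"], df["event"], df["score"])
        cp2 = cutpoint_sweep(df["time_months"], df["event"], np.exp(df["score"] / 20))
        assert np.allclose(cp1.table["statistic"], cp2.table["statistic"])
        assert cp2.optimal_cutpoint == pytest.approx(np.exp(cp1.optimal_cutpoint / 20))

    def test_min_prop_respected(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=100, seed=9))
        cp = cutpoint_sweep(df["time_months"], df["event"], df["score"], min_prop=0.2)
        assert (cp.table["n_high"] >= 20).all()
        assert (cp.table["n_low"] >= 20).all()

    def test_constant_score_rejected(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=30, seed=1))
        with pytest.raises(ValueError, match="constant"):
            cutpoint_sweep(df["time_months"], df["event"], np.ones(30))

    def test_maximally_selected_statistic_is_anticonservative(self):
        """Documented property: under the null the maximal |statistic|
        regularly exceeds the pointwise 1.96 threshold."""
        rng = np.random.default_rng(0)
        exceed = 0
        reps = 60
        for _ in range(reps):
            cfg = SurvivalConfig(
                n_subjects=80, log_hazard_per_unit=0.0,
                seed=int(rng.integers(2**31 - 1)),
            )
            df = generate_survival_cohort(cfg)
            cp = cutpoint_sweep(df["time_months"], df["event"], df["score"])
            exceed += abs(cp.optimal_statistic) > 1.96
        assert exceed / reps > 0.05  # far above the pointwise 2.5%


class TestCoxPH:
    def test_two_group_toy_matches_partial_likelihood_root(self):
        """Coefficient equals the root of the analytic two-group score
        equation (no ties)."""
        df = pd.DataFrame(
            {
                "time_months": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 1],
                "x": [1.0, 0.0, 1.0, 0.0],
            }
        )
        fit = cox_ph(df, ["x"])

        def score(beta):
            # risk sets at event times 1,2,3,4 with x = 1,0,1,0
            s = 0.0
            risk = [(1, [1, 0, 1, 0]), (0, [0, 1, 0]), (1, [1, 0]), (0, [0])]
            for xi, rset in risk:
                w = np.exp(beta * np.array(rset))
                s += xi - (np.array(rset) * w).sum() / w.sum()
            return s

        beta_hand = brentq(score, -10, 10, xtol=1e-12)
        assert fit.loc["x", "coef"] == pytest.approx(beta_hand, abs=1e-6)

    def test_matches_lifelines_multivariable(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=300, seed=11))
        fit = cox_ph(df, ["score", "age", "stage"])
        from lifelines import CoxPHFitter

        cph = CoxPHFitter()
        cph.fit(
            df[["time_months", "event", "score", "age", "stage"]],
            duration_col="time_months",
            event_col="event",
        )
        for cov in ["score", "age", "stage"]:
            assert fit.loc[cov, "coef"] == pytest.approx(
                cph.params_[cov], abs=1e-5
            )

    def test_breslow_ties_option_runs_and_differs(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=200, seed=12))
        df["time_months"] = df["time_months"].round()  # force ties
        df = df[df["time_months"] > 0]
        fe = cox_ph(df, ["score"], ties="efron")
        fb = cox_ph(df, ["score"], ties="breslow")
        assert fe.loc["score", "coef"] != fb.loc["score", "coef"]
        assert fe.loc["score", "HR"] > 0 and fb.loc["score", "HR"] > 0

    def test_horizon_censors_administratively(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=100, seed=13))
        h = apply_horizon(df, 48.0)
        assert (h["time_months"] <= 48.0).all()
        over = df["time_months"] > 48.0
        assert (h.loc[over, "event"] == 0).all()
        fit = cox_ph(df, ["score"], horizon_months=48.0)
        assert fit.attrs["horizon_months"] == 48.0

    def test_null_covariate_p_uniformish(self):
        rng = np.random.default_rng(1)
        rej = 0
        reps = 200
        for _ in range(reps):
            cfg = SurvivalConfig(
                n_subjects=120, log_hazard_per_unit=0.0,
                seed=int(rng.integers(2**31 - 1)),
            )
            df = generate_survival_cohort(cfg)
            fit = cox_ph(df, ["score"])
            rej += fit.loc["score", "p"] < 0.05
        assert 0.02 <= rej / reps <= 0.10

    def test_constant_covariate_rejected(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=50, seed=2))
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_ph(df, ["flat"])

    def test_ci_brackets_hr(self):
        df = generate_survival_cohort(SurvivalConfig(n_subjects=400, seed=3))
        fit = cox_ph(df, ["score", "age"])
        assert (fit["ci_lower"] <= fit["HR"]).all()
        assert (fit["HR"] <= fit["ci_upper"]).all()
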