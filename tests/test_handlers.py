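"""Tests of complete case analysis, chained-equations MI, and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import smartmiss as sm
from smartmiss.errors import EmptyAnalysisError, ParameterError
from smartmiss.handlers import (
    ImputationSpec,
    complete_case,
    default_m,
    mice_impute,
    pool_rubin,
)
from smartmiss.missingness import calibrated_config, impose_missingness
from smartmiss.simulate import TRIAL_COLUMNS


class TestCompleteCase:
    def test_identity_without_missingness(self, small_trial):
        out = complete_case(small_trial)
        pd.testing.assert_frame_equal(out, small_trial)

    def test_retains_responders_with_structural_a2(self, small_trial):
        cfg = calibrated_config(1, "weak", 0.2, calibration_n=100_000)
        inc = impose_missingness(small_trial, cfg, seed=4)
        out = complete_case(inc)
        kept_resp = out[out["R"] == 1]
        assert len(kept_resp) > 0
        assert kept_resp["A2"].isna().all()  # structural, not dropout

    def test_scenario3_expected_size(self, scenario3_incomplete):
        out = complete_case(scenario3_incomplete)
        n = len(scenario3_incomplete)
        # ~60% retained at 40% missingness; allow 4 binomial SDs
        tol = 4 * np.sqrt(0.4 * 0.6 * n)
        assert abs(len(out) - 0.6 * n) < tol
        assert out["O2"].notna().all() and out["Y"].notna().all()

    def test_empty_analysis_error(self, toy_trial):
        inc = toy_trial.assign(M_O2=0, M_A2=0, M_Y=1)
        with pytest.raises(EmptyAnalysisError):
            complete_case(inc)


class TestMice:
    def test_no_missingness_returns_identical_copies(self, small_trial):
        out = mice_impute(small_trial.assign(M_O2=0, M_A2=0, M_Y=0),
                          ImputationSpec(m=3, seed=1))
        assert len(out) == 3
        for d in out:
            pd.testing.assert_frame_equal(d, small_trial[TRIAL_COLUMNS])

    def test_observed_values_never_altered(self, scenario3_incomplete):
        inc = scenario3_incomplete
        for d in mice_impute(inc, ImputationSpec(m=2, iterations=2, seed=5)):
            for col, flag in [("O2", "M_O2"), ("Y", "M_Y")]:
                obs = inc[flag] == 0
                assert np.array_equal(d.loc[obs, col], inc.loc[obs, col])
            obs_a2 = (inc["M_A2"] == 0) & inc["A2"].notna()
            assert np.array_equal(d.loc[obs_a2, "A2"], inc.loc[obs_a2, "A2"])

    def test_completed_data_satisfy_design_invariants(self, scenario3_incomplete):
        for d in mice_impute(scenario3_incomplete, ImputationSpec(m=2, seed=9)):
            assert d["O2"].notna().all() and d["Y"].notna().all()
            assert ((d["O2"] <= 0).astype(int) == d["R"]).all()
            assert d.loc[d["R"] == 0, "A2"].isin([-1.0, 1.0]).all()
            assert d.loc[d["R"] == 1, "A2"].isna().all()
            # the completed data feed the estimator without error
            sm.fit_msm(sm.replicate_and_weight(d))

    def test_chains_reproducible_and_distinct(self, scenario3_incomplete):
        spec = ImputationSpec(m=2, iterations=2, seed=42)
        a = mice_impute(scenario3_incomplete, spec)
        b = mice_impute(scenario3_incomplete, spec)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert not a[0]["O2"].equals(a[1]["O2"])  # chains differ

    def test_mcar_pooled_estimates_unbiased(self):
        # scenario 1 is MCAR: pooled MI theta must be unbiased
        cfg = calibrated_config(1, "weak", 0.2, calibration_n=100_000)
        truth = sm.analytic_truth(0.1)
        thetas = []
        for i in range(60):
            trial = sm.generate_trial(sm.SimulationParams(400, 0.1, seed=7_000 + i))
            inc = impose_missingness(trial, cfg, seed=8_000 + i)
            betas = [
                sm.fit_msm(sm.replicate_and_weight(d)).beta
                for d in mice_impute(inc, ImputationSpec(m=3, seed=9_000 + i))
            ]
            thetas.append(sm.CONTRAST_MATRIX @ np.mean(betas, axis=0))
        thetas = np.array(thetas)
        mcse = thetas.std(axis=0, ddof=1) / np.sqrt(len(thetas))
        assert np.all(np.abs(thetas.mean(axis=0) - truth.theta) < 3 * mcse)

    def test_default_m_scales_with_missingness(self):
        assert default_m(0.2) == 20
        assert default_m(0.4) == 40

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            ImputationSpec(m=1)
        with pytest.raises(ParameterError):
            ImputationSpec(m=5, iterations=0)


class TestPoolRubin:
    def test_arithmetic_oracle(self):
        out = pool_rubin([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        (p,) = out
        assert p.point == pytest.approx(2.0)
        assert p.within_var == pytest.approx(1.0)
        assert p.between_var == pytest.approx(1.0)
        assert p.total_var == pytest.approx(1.0 + (1 + 1 / 3) * 1.0)

    def test_identical_estimates(self):
        (p,) = pool_rubin([2.0, 2.0, 2.0], [0.5, 0.5, 0.5])
        assert p.between_var == 0.0
        assert p.total_var == p.within_var
        assert np.isinf(p.df)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=10),
        st.floats(0.01, 4.0),
    )
    def test_total_at_least_within(self, estimates, var):
        (p,) = pool_rubin(estimates, [var] * len(estimates))
        assert p.total_var >= p.within_var

    def test_barnard_rubin_df_below_complete_df(self):
        (p,) = pool_rubin([1.0, 1.5, 2.5], [0.8, 1.1, 0.9], df_complete=50)
        assert 0 < p.df < 50
        lo, hi = p.ci(0.95)
        assert lo < p.point < hi

    def test_requires_two_imputations(self):
        with pytest.raises(ParameterError):
            pool_rubin([1.0], [1.0])
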