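"""Tests of responder replication, design weights, and the weighted MSM fit."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi
from hypothesis import given, settings, strategies as st

import smartmiss as sm
from smartmiss.errors import (
    IncompleteDataError,
    ParameterError,
    SingularDesignError,
)
from smartmiss.estimator import _fit_participants, _participant_arrays


def _make_trial(r_flags, seed=0):
    rng = np.random.default_rng(seed)
    n = len(r_flags)
    r = np.asarray(r_flags)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "O1": rng.standard_normal(n),
            "A1": rng.choice([-1.0, 1.0], n),
            "O2": np.where(r == 1, -0.5, 0.5),
            "R": r,
            "A2": np.where(r == 0, rng.choice([-1.0, 1.0], n), np.nan),
            "Y": rng.standard_normal(n),
        }
    )


class TestReplicateAndWeight:
    def test_toy_counts_and_weights(self, toy_trial):
        rep = sm.replicate_and_weight(toy_trial)
        assert len(rep) == 3
        resp_rows = rep[rep["id"] == 0]
        assert len(resp_rows) == 2
        assert set(resp_rows["A2"]) == {-1.0, 1.0}
        assert (resp_rows["weight"] == 2.0).all()
        assert (rep.loc[rep["id"] == 1, "weight"] == 4.0).all()

    def test_all_nonresponders_pass_through(self):
        trial = _make_trial(np.zeros(8, dtype=int))
        rep = sm.replicate_and_weight(trial)
        assert len(rep) == 8
        assert (rep["weight"] == 4.0).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=50))
    def test_total_weight_is_4n(self, r_flags):
        trial = _make_trial(r_flags)
        rep = sm.replicate_and_weight(trial)
        assert rep["weight"].sum() == 4 * len(trial)
        assert len(rep) == len(trial) + sum(r_flags)

    def test_rejects_incomplete_rows(self, toy_trial):
        broken = toy_trial.copy()
        broken.loc[1, "A2"] = np.nan  # non-responder without stage-2 treatment
        with pytest.raises(IncompleteDataError, match="missing-data method"):
            sm.replicate_and_weight(broken)
        broken = toy_trial.copy()
        broken.loc[0, "Y"] = np.nan
        with pytest.raises(IncompleteDataError):
            sm.replicate_and_weight(broken)


class TestFitMSM:
    def test_hand_solved_toy(self):
        # weighted normal equations solved by hand for a balanced 4-row design
        data = pd.DataFrame(
            {
                "id": [0, 1, 2, 3],
                "A1": [1.0, 1.0, -1.0, -1.0],
                "A2": [1.0, -1.0, 1.0, -1.0],
                "R": 0,
                "weight": 4.0,
                "Y": [2.0, 0.0, 1.0, 1.0],
            }
        )
        fit = sm.fit_msm(data)
        assert np.allclose(fit.beta, [1.0, 0.0, 0.5])

    def test_constant_outcome(self, small_trial):
        trial = small_trial.copy()
        trial["Y"] = 7.0
        fit = sm.fit_msm(sm.replicate_and_weight(trial))
        assert np.allclose(fit.beta, [7.0, 0.0, 0.0], atol=1e-12)

    def test_matches_statsmodels_gee_independence(self, small_trial):
        # independent route: GEE with independence working correlation
        rep = sm.replicate_and_weight(small_trial)
        fit = sm.fit_msm(rep)
        gee = smapi.GEE(
            rep["Y"],
            smapi.add_constant(rep[["A1", "A2"]]),
            groups=rep["id"],
            weights=rep["weight"],
            cov_struct=smapi.cov_struct.Independence(),
        ).fit()
        assert np.allclose(fit.beta, gee.params.to_numpy(), atol=1e-8)

    def test_row_order_and_weight_split_invariance(self, small_trial):
        rep = sm.replicate_and_weight(small_trial)
        beta = sm.fit_msm(rep).beta
        shuffled = rep.sample(frac=1.0, random_state=1)
        assert np.allclose(sm.fit_msm(shuffled).beta, beta)
        # split every weight-4 row into two weight-2 rows
        w4 = rep[rep["weight"] == 4.0].assign(weight=2.0)
        split = pd.concat([rep[rep["weight"] == 2.0], w4, w4])
        assert np.allclose(sm.fit_msm(split).beta, beta)

    def test_singular_cell_named(self):
        trial = _make_trial(np.zeros(6, dtype=int), seed=3)
        trial["A1"] = 1.0  # empty A1 = -1 cells
        with pytest.raises(SingularDesignError, match=r"A1=-1"):
            sm.fit_msm(sm.replicate_and_weight(trial))

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            sm.fit_msm(pd.DataFrame(columns=["id", "A1", "A2", "R", "weight", "Y"]))

    def test_fast_path_matches_frame_path(self, small_trial):
        beta_frame = sm.fit_msm(sm.replicate_and_weight(small_trial)).beta
        beta_fast = _fit_participants(*_participant_arrays(small_trial))
        assert np.allclose(beta_frame, beta_fast)


class TestContrasts:
    @pytest.mark.parametrize(
        "beta,theta",
        [
            ([1, 0, 0], [1, 1, 1, 1]),
            ([0, 1, 0], [1, 1, -1, -1]),
            ([1.25, -0.15, 0.03], [1.13, 1.07, 1.43, 1.37]),
        ],
    )
    def test_theta_from_beta(self, beta, theta):
        fit = sm.MSMFit(beta=np.array(beta, float), n_participants=1, n_rows=1)
        assert np.allclose(sm.theta_from_beta(fit).theta, theta)

    def test_dtr_difference_identity(self, small_trial):
        # theta1 - theta2 = theta3 - theta4 = 2*beta2 by construction
        fit = sm.fit_msm(sm.replicate_and_weight(small_trial))
        th = sm.theta_from_beta(fit).theta
        assert th[0] - th[1] == pytest.approx(th[2] - th[3])
        assert th[0] - th[1] == pytest.approx(2 * fit.beta[2])


class TestBootstrap:
    def test_constant_outcome_gives_zero_se(self, small_trial):
        trial = small_trial.copy()
        trial["Y"] = 3.0
        bs = sm.bootstrap_se(trial, "none", B=20, seed=2)
        assert np.allclose(bs["beta_se"], 0.0)
        assert np.allclose(bs["theta_se"], 0.0)

    def test_seed_reproducibility(self, scenario3_incomplete):
        a = sm.bootstrap_se(scenario3_incomplete, "cca", B=30, seed=6)
        b = sm.bootstrap_se(scenario3_incomplete, "cca", B=30, seed=6)
        assert np.array_equal(a["beta_se"], b["beta_se"])

    def test_invalid_inputs(self, small_trial):
        with pytest.raises(ParameterError):
            sm.bootstrap_se(small_trial, "none", B=1, seed=0)
        with pytest.raises(ParameterError):
            sm.bootstrap_se(small_trial, "magic", B=10, seed=0)


def test_beta01_covariance_drives_se_ordering():
    """Across complete-data replicates cov(b0, b1) > 0, so the DTR means
    sharing the +A1 contrast (DTR1, DTR2) are noisier than DTR3, DTR4."""
    betas = []
    for i in range(300):
        trial = sm.generate_trial(sm.SimulationParams(400, 0.1, seed=1_000 + i))
        betas.append(sm.fit_msm(sm.replicate_and_weight(trial)).beta)
    betas = np.array(betas)
    assert np.cov(betas[:, 0], betas[:, 1])[0, 1] > 0
    thetas = betas @ sm.CONTRAST_MATRIX.T
    se = thetas.std(axis=0, ddof=1)
    assert min(se[0], se[1]) > max(se[2], se[3])
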