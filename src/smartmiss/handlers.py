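"""Missing-data handlers: complete case analysis and chained-equations MI.

Complete case analysis keeps exactly the participants with no
dropout-induced missingness; a responder's structurally absent ``A2`` is
a design feature, not a missing value, and never causes exclusion.

Multiple imputation cycles through one conditional model per incomplete
variable (chained equations):

* ``Y  | O1, A1, A2, O2`` — linear regression
* ``O2 | O1, A1, A2, Y``  — linear regression
* ``A2 | O1, A1, O2, Y``  — logistic regression

Imputations are *proper*: each cycle draws the model parameters from
their approximate posterior (normal-theory draws with a scaled
inverse-chi-square variance draw for the linear models, asymptotic-normal
coefficient draws for the logistic model) before drawing values, so
parameter uncertainty propagates into the imputations.

Responder status ``R`` is never imputed directly: it is recomputed
passively from the current ``O2`` after each update, and ``A2`` is
imputed only for records whose current ``O2 > 0`` (non-responders).
Records whose current ``O2 <= 0`` carry the structural not-applicable
``A2``; where ``A2`` enters another imputation model as a predictor, the
structural state is zero-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import t as t_dist

from .errors import EmptyAnalysisError, ParameterError
from .missingness import MISSINGNESS_COLUMNS
from .simulate import TRIAL_COLUMNS

logger = logging.getLogger(__name__)


def default_m(target_proportion: float) -> int:
    """Number of imputations scaled to the missingness proportion.

    20 imputed datasets for roughly 20% missingness, 40 for roughly 40%.
    """
    return 40 if target_proportion >= 0.3 else 20


@dataclass(frozen=True)
class ImputationSpec:
    """Settings for one chained-equations run.

    ``stratify_by_stage1`` fits every imputation model separately within
    each stage-1 arm (the default).  The outcome surface contains a
    stage-1-treatment-by-baseline interaction, so a pooled main-effects
    imputation model is incompatible with the analysis and leaves
    systematic bias in the imputations; within-arm models are exactly
    specified.  Set to False to use a single pooled model per variable.
    """

    m: int = 20
    iterations: int = 5
    seed: int = 0
    stratify_by_stage1: bool = True

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ParameterError(f"m must be >= 2, got {self.m}")
        if self.iterations < 1:
            raise ParameterError(f"iterations must be >= 1, got {self.iterations}")


def complete_case(incomplete: pd.DataFrame) -> pd.DataFrame:
    """Drop every participant with any dropout-induced missing value.

    Input without ``M_*`` indicator columns is treated as complete and
    returned unchanged (as a copy restricted to the trial schema).
    """
    if not all(c in incomplete.columns for c in MISSINGNESS_COLUMNS):
        return incomplete[TRIAL_COLUMNS].copy()
    keep = (
        (incomplete["M_O2"] == 0)
        & (incomplete["M_A2"] == 0)
        & (incomplete["M_Y"] == 0)
    )
    if not keep.any():
        raise EmptyAnalysisError("no complete cases remain")
    return incomplete.loc[keep, TRIAL_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# chained equations


def _draw_linear(rng, x_obs, y_obs, x_mis):
    """Proper imputation draw for a linear model.

    Fits OLS on the observed rows, draws sigma^2 from its scaled
    inverse-chi-square posterior and beta from N(beta_hat, sigma^2 (X'X)^-1),
    then draws imputed values with residual noise.
    """
    n, k = x_obs.shape
    beta_hat, _, _, _ = np.linalg.lstsq(x_obs, y_obs, rcond=None)
    resid = y_obs - x_obs @ beta_hat
    df = max(n - k, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    xtx_inv = np.linalg.pinv(x_obs.T @ x_obs)
    cov = sigma2 * xtx_inv
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    return x_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), len(x_mis))


def _fit_logistic(x, y01, ridge=0.0, max_iter=50, tol=1e-8):
    """IRLS logistic fit returning (coef, covariance).

    ``ridge`` adds an L2 penalty on all coefficients; used as a fallback
    when the unpenalised fit separates or fails to converge.
    """
    k = x.shape[1]
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = x @ beta
        p = expit(eta)
        w = p * (1 - p)
        h = x.T @ (x * w[:, None]) + ridge * np.eye(k)
        grad = x.T @ (y01 - p) - ridge * beta
        step = np.linalg.solve(h, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = x @ beta
    p = expit(eta)
    w = p * (1 - p)
    cov = np.linalg.inv(x.T @ (x * w[:, None]) + ridge * np.eye(k))
    return beta, cov


def _draw_logistic(rng, x_obs, y_obs_pm1, x_mis):
    """Proper imputation draw for the -1/+1 binary A2.

    Draws coefficients from their asymptotic normal distribution, then
    Bernoulli values.  Separation (non-finite or exploding estimates)
    falls back to a weakly penalised fit.
    """
    y01 = (y_obs_pm1 == 1.0).astype(float)
    try:
        beta_hat, cov = _fit_logistic(x_obs, y01)
        if not (np.all(np.isfinite(beta_hat)) and np.all(np.isfinite(cov))) or np.max(
            np.abs(beta_hat)
        ) > 30:
            raise np.linalg.LinAlgError("separation suspected")
    except np.linalg.LinAlgError:
        logger.warning("logistic imputation model separation; using penalised fit")
        beta_hat, cov = _fit_logistic(x_obs, y01, ridge=1e-2)
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    p = expit(x_mis @ beta)
    return np.where(rng.random(len(x_mis)) < p, 1.0, -1.0)


def _impute_chain(
    incomplete: pd.DataFrame, iterations: int, rng, stratify: bool = True
) -> pd.DataFrame:
    """Run one chained-equations chain and return the completed dataset."""
    o1 = incomplete["O1"].to_numpy(dtype=float)
    a1 = incomplete["A1"].to_numpy(dtype=float)
    o2 = incomplete["O2"].to_numpy(dtype=float).copy()
    a2 = incomplete["A2"].to_numpy(dtype=float).copy()
    y = incomplete["Y"].to_numpy(dtype=float).copy()
    miss_o2 = incomplete["M_O2"].to_numpy() == 1
    ev_a2 = incomplete["M_A2"].to_numpy() == 1  # dropout event, not structural NA
    miss_y = incomplete["M_Y"].to_numpy() == 1
    obs_a2_mask = ~ev_a2 & np.isfinite(a2)  # originally observed non-responder A2

    if miss_o2.all():
        raise ParameterError("O2 has no observed values; cannot impute")
    if miss_y.all():
        raise ParameterError("Y has no observed values; cannot impute")
    if ev_a2.any() and not obs_a2_mask.any():
        raise ParameterError("A2 has no observed values; cannot impute")

    # within a stage-1 arm A1 is constant, so it leaves the design matrix
    if stratify:
        groups = [a1 == 1.0, a1 == -1.0]
        arm_col = ()
    else:
        groups = [np.ones_like(a1, dtype=bool)]
        arm_col = (a1,)

    def a2_zero_coded():
        return np.where(np.isfinite(a2), a2, 0.0)

    def impute_linear(target, miss, predictors):
        x = np.column_stack([np.ones_like(o1), o1, *arm_col, *predictors])
        for g in groups:
            fit, put = g & ~miss, g & miss
            if put.any():
                target[put] = _draw_linear(rng, x[fit], target[fit], x[put])

    # initial fill: draws from the observed marginals
    o2[miss_o2] = rng.choice(o2[~miss_o2], miss_o2.sum(), replace=True)
    y[miss_y] = rng.choice(y[~miss_y], miss_y.sum(), replace=True)
    need_a2 = ev_a2 & (o2 > 0)
    if need_a2.any():
        a2[need_a2] = rng.choice(a2[obs_a2_mask], need_a2.sum(), replace=True)
    a2[ev_a2 & (o2 <= 0)] = np.nan

    for _ in range(iterations):
        # O2 | O1, (A1), A2(zero-coded), Y  — linear
        if miss_o2.any():
            impute_linear(o2, miss_o2, (a2_zero_coded(), y))
            # passive responder update: structural A2 follows the current O2
            a2[ev_a2 & (o2 <= 0)] = np.nan
        # A2 | O1, (A1), O2, Y  — logistic, non-responders by current O2 only
        need_a2 = ev_a2 & (o2 > 0)
        if need_a2.any():
            x = np.column_stack([np.ones_like(o1), o1, *arm_col, o2, y])
            for g in groups:
                fit, put = g & obs_a2_mask, g & need_a2
                if put.any():
                    a2[put] = _draw_logistic(rng, x[fit], a2[fit], x[put])
        # Y | O1, (A1), A2(zero-coded), O2  — linear
        if miss_y.any():
            impute_linear(y, miss_y, (a2_zero_coded(), o2))

    completed = pd.DataFrame(
        {
            "id": incomplete["id"].to_numpy(),
            "O1": o1,
            "A1": a1,
            "O2": o2,
            "R": (o2 <= 0).astype(int),
            "A2": np.where(o2 > 0, a2, np.nan),
            "Y": y,
        }
    )
    return completed


def mice_impute(incomplete: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations.

    Returns ``spec.m`` completed datasets (trial schema).  All chains use
    independent substreams of ``spec.seed``; observed values are never
    altered.  Input without missingness returns ``m`` identical copies.
    """
    has_indicators = all(c in incomplete.columns for c in MISSINGNESS_COLUMNS)
    if not has_indicators or not (
        incomplete[MISSINGNESS_COLUMNS].to_numpy().any()
    ):
        return [incomplete[TRIAL_COLUMNS].copy() for _ in range(spec.m)]
    ss = np.random.SeedSequence(spec.seed)
    completed = []
    for chain in range(spec.m):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(chain,))
        )
        completed.append(
            _impute_chain(incomplete, spec.iterations, rng, spec.stratify_by_stage1)
        )
    return completed


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of one parameter across imputations."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        se = np.sqrt(self.total_var)
        if np.isinf(self.df):
            from scipy.stats import norm

            q = norm.ppf(0.5 + level / 2.0)
        else:
            q = t_dist.ppf(0.5 + level / 2.0, self.df)
        return (self.point - q * se, self.point + q * se)


def pool_rubin(
    per_imputation_estimates,
    per_imputation_variances,
    df_complete: float | None = None,
) -> list[PooledEstimate]:
    """Pool per-imputation estimates and variances by Rubin's rules.

    ``total_var = within + (1 + 1/m) * between``; degrees of freedom by
    the Barnard–Rubin small-sample formula when ``df_complete`` (the
    complete-data degrees of freedom) is supplied, else the classic
    large-sample formula.  Returns one :class:`PooledEstimate` per
    parameter (column).
    """
    est = np.asarray(per_imputation_estimates, dtype=float)
    var = np.asarray(per_imputation_variances, dtype=float)
    if est.ndim == 1:
        est = est[:, None]
    if var.ndim == 1:
        var = var[:, None]
    m = est.shape[0]
    if m < 2:
        raise ParameterError("Rubin pooling requires m >= 2 imputations")
    if var.shape != est.shape:
        raise ParameterError("estimates and variances must align")

    out = []
    for j in range(est.shape[1]):
        q = est[:, j]
        u = var[:, j]
        point = float(q.mean())
        w = float(u.mean())
        b = float(q.var(ddof=1))
        total = w + (1.0 + 1.0 / m) * b
        lam = (1.0 + 1.0 / m) * b / total if total > 0.0 else 0.0
        if lam <= 0.0 or lam * lam == 0.0:  # underflow guard
            df = np.inf if df_complete is None else float(df_complete)
        else:
            nu_old = (m - 1) / lam**2
            if df_complete is None:
                df = nu_old
            else:
                nu_obs = (
                    (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
                )
                df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        out.append(
            PooledEstimate(
                point=point,
                within_var=w,
                between_var=b,
                total_var=total,
                df=float(df),
                m=m,
            )
        )
    return out
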