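"""IPW estimation of DTR means via responder replication and weighted GEE.

Responders are consistent with two embedded regimens (their A2 is never
realised), so their rows are duplicated — one copy with ``A2 = -1``, one
with ``A2 = +1`` — before estimation.  Inverse probability weights are
the reciprocal probability of the observed treatment path: non-responders
are randomised twice, weight ``1/(0.5*0.5) = 4``; responders once, weight
``1/0.5 = 2`` on each replicated row.

The marginal structural model ``E[Y(d)] = beta0 + beta1*A1 + beta2*A2``
is fitted by weighted estimating equations with an independence working
correlation, which for a linear model is numerically identical to
weighted least squares of Y on (1, A1, A2); clustering of replicated rows
by participant affects only the variance, never the point estimate.
Reported model-based standard errors come from a cluster bootstrap that
resamples participants (so a responder's two pseudo-rows always travel
together); a cluster-robust sandwich covariance is also exposed for
diagnostics and for within-imputation variance in Rubin pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    BootstrapDegeneracyError,
    IncompleteDataError,
    ParameterError,
    SingularDesignError,
)
from .simulate import CONTRAST_MATRIX, P_STAGE1, P_STAGE2

__all__ = [
    "CONTRAST_MATRIX",
    "MSMFit",
    "DTREstimates",
    "replicate_and_weight",
    "fit_msm",
    "theta_from_beta",
    "cluster_robust_cov",
    "bootstrap_se",
]

#: Weight for a non-responder (randomised at both stages).
WEIGHT_NONRESPONDER = 1.0 / (P_STAGE1 * P_STAGE2)
#: Weight for each replicated responder row (randomised once).
WEIGHT_RESPONDER = 1.0 / P_STAGE1

REPLICATED_COLUMNS = ["id", "A1", "A2", "R", "weight", "Y"]


@dataclass(frozen=True)
class MSMFit:
    beta: np.ndarray
    n_participants: int
    n_rows: int
    converged: bool = True

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", beta)
        if not np.all(np.isfinite(beta)):
            raise ParameterError(f"non-finite MSM coefficients: {beta}")


@dataclass(frozen=True)
class DTREstimates:
    theta: np.ndarray
    contrast_matrix: np.ndarray = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if self.contrast_matrix is None:
            object.__setattr__(self, "contrast_matrix", CONTRAST_MATRIX.copy())


def replicate_and_weight(trial: pd.DataFrame) -> pd.DataFrame:
    """Expand a complete (or completed) trial into the weighted analysis table.

    Every participant must have observed ``R`` and ``Y``, and non-responders
    an observed ``A2``; incomplete data must be handled (complete case
    analysis or imputation) before estimation.

    Returns one row per (participant, consistent-regimen path):
    non-responders keep their single row with weight 4; responders get two
    rows, ``A2 = -1`` and ``A2 = +1``, each with weight 2.
    """
    r = trial["R"].to_numpy(dtype=float)
    y = trial["Y"].to_numpy(dtype=float)
    a2 = trial["A2"].to_numpy(dtype=float)
    bad = ~np.isfinite(r) | ~np.isfinite(y) | ((r == 0) & ~np.isfinite(a2))
    if np.any(bad):
        raise IncompleteDataError(
            f"{int(bad.sum())} row(s) have unresolved R, missing Y, or a "
            "non-responder with missing A2; apply a missing-data method "
            "(complete_case or mice_impute) before estimation"
        )

    resp = trial[r == 1]
    nonresp = trial[r == 0]
    n_resp = len(resp)

    rows = pd.concat(
        [
            pd.DataFrame(
                {
                    "id": nonresp["id"].to_numpy(),
                    "A1": nonresp["A1"].to_numpy(dtype=float),
                    "A2": nonresp["A2"].to_numpy(dtype=float),
                    "R": 0,
                    "weight": WEIGHT_NONRESPONDER,
                    "Y": nonresp["Y"].to_numpy(dtype=float),
                }
            ),
            pd.DataFrame(
                {
                    "id": np.tile(resp["id"].to_numpy(), 2),
                    "A1": np.tile(resp["A1"].to_numpy(dtype=float), 2),
                    "A2": np.repeat([1.0, -1.0], n_resp),
                    "R": 1,
                    "weight": WEIGHT_RESPONDER,
                    "Y": np.tile(resp["Y"].to_numpy(dtype=float), 2),
                }
            ),
        ],
        ignore_index=True,
    )
    return rows[REPLICATED_COLUMNS]


def _solve_wls(a1: np.ndarray, a2: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve the weighted normal equations for Y ~ 1 + A1 + A2."""
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            if w[(a1 == s1) & (a2 == s2)].sum() <= 0.0:
                raise SingularDesignError(
                    f"treatment cell (A1={s1:+.0f}, A2={s2:+.0f}) carries zero weight"
                )
    x = np.column_stack([np.ones_like(a1), a1, a2])
    xtw = (x * w[:, None]).T
    return np.linalg.solve(xtw @ x, xtw @ y)


def fit_msm(data: pd.DataFrame) -> MSMFit:
    """Fit the MSM on a replicated, weighted analysis table.

    Weighted least squares solves the independence-working-correlation
    estimating equations exactly; no iterative GEE machinery is needed.
    Raises :class:`SingularDesignError` if any (A1, A2) cell has zero
    total weight.
    """
    if len(data) == 0:
        raise ParameterError("empty analysis table")
    beta = _solve_wls(
        data["A1"].to_numpy(dtype=float),
        data["A2"].to_numpy(dtype=float),
        data["Y"].to_numpy(dtype=float),
        data["weight"].to_numpy(dtype=float),
    )
    return MSMFit(
        beta=beta,
        n_participants=int(data["id"].nunique()),
        n_rows=len(data),
    )


def theta_from_beta(fit: MSMFit) -> DTREstimates:
    """Map MSM coefficients to the four DTR means, theta = C @ beta."""
    return DTREstimates(theta=CONTRAST_MATRIX @ fit.beta)


def cluster_robust_cov(data: pd.DataFrame, beta: np.ndarray | None = None) -> np.ndarray:
    """Sandwich covariance of beta with clustering by participant id.

    Diagnostics only; reported model-based SEs come from the cluster
    bootstrap.
    """
    a1 = data["A1"].to_numpy(dtype=float)
    a2 = data["A2"].to_numpy(dtype=float)
    y = data["Y"].to_numpy(dtype=float)
    w = data["weight"].to_numpy(dtype=float)
    ids = data["id"].to_numpy()
    if beta is None:
        beta = _solve_wls(a1, a2, y, w)
    x = np.column_stack([np.ones_like(a1), a1, a2])
    bread = np.linalg.inv((x * w[:, None]).T @ x)
    resid = y - x @ beta
    score = x * (w * resid)[:, None]
    # sum scores within cluster, then take outer products
    df = pd.DataFrame(score, index=ids)
    g = df.groupby(level=0).sum().to_numpy()
    meat = g.T @ g
    return bread @ meat @ bread


# ---------------------------------------------------------------------------
# Cluster bootstrap


def _participant_arrays(trial: pd.DataFrame):
    """Per-participant numpy views used by the bootstrap fast path."""
    return (
        trial["A1"].to_numpy(dtype=float),
        trial["R"].to_numpy(dtype=float),
        trial["A2"].to_numpy(dtype=float),
        trial["Y"].to_numpy(dtype=float),
    )

def _fit_participants(a1, r, a2, y) -> np.ndarray:
    """Replicate responders and fit, working on per-participant arrays.

    Equivalent to ``fit_msm(replicate_and_weight(trial)).beta``; kept as a
    frame-free path so the bootstrap stays cheap.
    """
    resp = r == 1
    nr = ~resp
    n_resp = int(resp.sum())
    ra1 = np.concatenate([a1[nr], np.tile(a1[resp], 2)])
    ra2 = np.concatenate([a2[nr], np.repeat([1.0, -1.0], n_resp)])
    ry = np.concatenate([y[nr], np.tile(y[resp], 2)])
    rw = np.concatenate(
        [
            np.full(int(nr.sum()), WEIGHT_NONRESPONDER),
            np.full(2 * n_resp, WEIGHT_RESPONDER),
        ]
    )
    return _solve_wls(ra1, ra2, ry, rw)


def bootstrap_se(
    trial: pd.DataFrame,
    handler: str = "none",
    B: int = 200,
    seed: int = 0,
    mi_m: int = 5,
    mi_iterations: int = 5,
    retry_cap: int = 50,
) -> dict:
    """Cluster bootstrap standard errors for beta and theta.

    Participants (clusters, pre-replication) are resampled with
    replacement ``B`` times; the configured missing-data handler and the
    full estimation pipeline are re-run on each resample, and the SE is
    the standard deviation of the ``B`` estimates.  Resamples with a
    singular replicated design are redrawn, up to ``retry_cap`` redraws
    per slot, and counted in the returned diagnostics.

    Parameters
    ----------
    trial
        Complete trial data (``handler="none"``) or incomplete data with
        ``M_*`` indicator columns (``handler="cca"`` or ``"mi"``).
    handler
        ``none`` | ``cca`` | ``mi``.  With ``mi`` each resample is
        re-imputed with ``mi_m`` imputations and the pooled point
        estimate is bootstrapped.
    """
    if B < 2:
        raise ParameterError("B must be >= 2")
    if handler not in ("none", "cca", "mi"):
        raise ParameterError(f"unknown handler {handler!r}")
    n = len(trial)
    rng = np.random.default_rng(seed)
    betas = np.empty((B, 3))
    n_redraws = 0

    if handler in ("none", "cca"):
        if handler == "cca":
            complete = (
                (trial["M_O2"].to_numpy() == 0)
                & (trial["M_A2"].to_numpy() == 0)
                & (trial["M_Y"].to_numpy() == 0)
            )
        else:
            complete = np.ones(n, dtype=bool)
        a1, r, a2, y = _participant_arrays(trial)
        for b in range(B):
            for attempt in range(retry_cap + 1):
                idx = rng.integers(0, n, n)
                keep = idx[complete[idx]]
                try:
                    betas[b] = _fit_participants(a1[keep], r[keep], a2[keep], y[keep])
                    break
                except SingularDesignError:
                    n_redraws += 1
            else:
                raise BootstrapDegeneracyError(
                    f"bootstrap slot {b}: {retry_cap} consecutive singular resamples "
                    f"(n={n}, handler={handler})"
                )
    else:  # mi
        from .handlers import ImputationSpec, mice_impute

        for b in range(B):
            for attempt in range(retry_cap + 1):
                idx = rng.integers(0, n, n)
                resample = trial.iloc[idx].copy()
                resample["id"] = np.arange(n)  # resampled clusters get fresh ids
                spec = ImputationSpec(
                    m=mi_m,
                    iterations=mi_iterations,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                try:
                    completed = mice_impute(resample, spec)
                    imp_betas = np.array(
                        [
                            fit_msm(replicate_and_weight(d)).beta
                            for d in completed
                        ]
                    )
                    betas[b] = imp_betas.mean(axis=0)
                    break
                except SingularDesignError:
                    n_redraws += 1
            else:
                raise BootstrapDegeneracyError(
                    f"bootstrap slot {b}: {retry_cap} consecutive singular resamples "
                    f"(n={n}, handler={handler})"
                )

    thetas = betas @ CONTRAST_MATRIX.T
    return {
        "beta_se": betas.std(axis=0, ddof=1),
        "theta_se": thetas.std(axis=0, ddof=1),
        "n_redraws": n_redraws,
        "B": B,
    }
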