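"""Simulation performance measures with Monte Carlo errors.

For each parameter (the three MSM coefficients and the four DTR means)
the summary reports bias (mean estimate minus truth), the empirical
standard error (SD of the estimates across replicates), the model-based
standard error (mean of the per-replicate bootstrap SEs), and the
coverage of nominal confidence intervals, each with its Monte Carlo
standard error:

    mcse(bias)     = empSE / sqrt(n_rep)
    mcse(empSE)    = empSE / sqrt(2 (n_rep - 1))
    mcse(coverage) = sqrt(cov (1 - cov) / n_rep)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .errors import ParameterError
from .simulate import PARAMETER_NAMES, TruthValues


@dataclass(frozen=True)
class PerformanceSummary:
    parameter: str
    truth: float
    bias: float
    abs_bias: float
    empirical_se: float
    model_se: float
    coverage: float
    mcse_bias: float
    mcse_empse: float
    mcse_coverage: float
    n_replicates: int


def summarize(
    estimates,
    ses,
    truth: TruthValues,
    ci_level: float = 0.95,
    parameter_names: list[str] | None = None,
    t_df=None,
) -> pd.DataFrame:
    """Summarise per-replicate estimates against the truth.

    Parameters
    ----------
    estimates
        Array-like of shape (n_replicates, n_parameters), or a DataFrame
        whose columns name the parameters.
    ses
        Per-replicate model SEs, aligned with ``estimates``; may contain
        NaN (e.g. a bias-only run), in which case model SE and coverage
        are NaN.
    truth
        Reference values; its vector order must match the columns.
    t_df
        Optional degrees of freedom per replicate-parameter (same shape)
        for t-based intervals (Rubin pooling); default normal quantiles.

    Returns a tidy DataFrame with one :class:`PerformanceSummary` row per
    parameter; replicate order is immaterial.
    """
    if isinstance(estimates, pd.DataFrame):
        parameter_names = list(estimates.columns)
        estimates = estimates.to_numpy(dtype=float)
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.ndim != 2 or se.shape != est.shape:
        raise ParameterError(
            f"estimates and ses must be aligned 2-D arrays, got {est.shape} vs {se.shape}"
        )
    n_rep, n_par = est.shape
    if n_rep < 2:
        raise ParameterError("need at least 2 replicates")
    if parameter_names is None:
        parameter_names = PARAMETER_NAMES[:n_par]
    truth_vec = truth.as_vector()[:n_par] if isinstance(truth, TruthValues) else np.asarray(truth, float)

    q = norm.ppf(0.5 + ci_level / 2.0)
    if t_df is not None:
        q = t_dist.ppf(0.5 + ci_level / 2.0, np.asarray(t_df, dtype=float))

    rows = []
    for j, name in enumerate(parameter_names):
        e = est[:, j]
        s = se[:, j]
        qj = q if np.ndim(q) == 0 else q[:, j]
        bias = float(e.mean() - truth_vec[j])
        emp_se = float(e.std(ddof=1))
        if np.all(np.isfinite(s)):
            model_se = float(s.mean())
            covered = (e - qj * s <= truth_vec[j]) & (truth_vec[j] <= e + qj * s)
            cov = float(covered.mean())
            mcse_cov = float(np.sqrt(cov * (1.0 - cov) / n_rep))
        else:
            model_se, cov, mcse_cov = float("nan"), float("nan"), float("nan")
        rows.append(
            PerformanceSummary(
                parameter=name,
                truth=float(truth_vec[j]),
                bias=bias,
                abs_bias=abs(bias),
                empirical_se=emp_se,
                model_se=model_se,
                coverage=cov,
                mcse_bias=emp_se / np.sqrt(n_rep),
                mcse_empse=emp_se / np.sqrt(2.0 * (n_rep - 1)),
                mcse_coverage=mcse_cov,
                n_replicates=n_rep,
            )
        )
    return pd.DataFrame([asdict(r) for r in rows])
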