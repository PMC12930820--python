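"""Factorial simulation experiment: scenarios x proportions x strengths x methods.

Each cell of the grid runs ``n_replicates`` independent replicates of
generate -> impose missingness -> handle (CCA or MI) -> replicate/weight
-> fit -> DTR contrasts -> model SE, then summarises performance against
the analytic truth.  Seed streams are keyed by (master seed, cell,
replicate index), never by worker, so results are bit-identical for any
worker count and each replicate is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .errors import SmartmissError
from .estimator import (
    CONTRAST_MATRIX,
    bootstrap_se,
    cluster_robust_cov,
    fit_msm,
    replicate_and_weight,
    theta_from_beta,
)
from .handlers import ImputationSpec, complete_case, default_m, mice_impute, pool_rubin
from .missingness import calibrate_intercept, impose_missingness, make_config
from .performance import summarize
from .simulate import PARAMETER_NAMES, SimulationParams, analytic_truth, generate_trial

SCENARIOS = (1, 2, 3, 4)
PROPORTIONS = (0.2, 0.4)
STRENGTHS = ("weak", "strong")
METHODS = ("cca", "mi")


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for a (sub)grid run; the defaults are the full design."""

    n_participants: int = 400
    n_replicates: int = 1000
    delta: float = 0.1
    scenarios: tuple = SCENARIOS
    proportions: tuple = PROPORTIONS
    strengths: tuple = STRENGTHS
    methods: tuple = METHODS
    bootstrap_B: int = 200
    mi_m: int | None = None  # None -> scaled to the missingness proportion
    mi_iterations: int = 5
    mi_mode: str = "bootstrap_wrapped"  # or "rubin"
    mi_bootstrap_m: int = 5  # reduced imputation count inside each bootstrap resample
    calibration_n: int = 1_000_000
    master_seed: int = 20_210_101
    workers: int = 1

    def grid(self) -> list[tuple]:
        return [
            (s, p, st, m)
            for s in self.scenarios
            for p in self.proportions
            for st in self.strengths
            for m in self.methods
        ]


def _cell_key(cell: tuple) -> str:
    s, p, st, m = cell
    return f"sc{s}_p{int(round(p * 100))}_{st}_{m}"


def _cell_index(cell: tuple) -> int:
    """Stable integer identifying a cell in the seed stream, independent of
    which subset of the grid is being run."""
    s, p, st, m = cell
    return (
        s * 1_000_000
        + int(round(p * 100)) * 1_000
        + STRENGTHS.index(st) * 10
        + METHODS.index(m)
    )


def _one_replicate(config: ExperimentConfig, cell: tuple, cal_alpha0: float, rep: int):
    """Run a single replicate of a cell; returns (estimates, ses, t_df, error)."""
    scenario, proportion, strength, method = cell
    ss = np.random.SeedSequence(
        entropy=config.master_seed, spawn_key=(_cell_index(cell), rep)
    )
    s_gen, s_miss, s_handle, s_boot = ss.spawn(4)
    nan7 = np.full(7, np.nan)
    try:
        trial = generate_trial(
            SimulationParams(config.n_participants, config.delta, seed=s_gen)
        )
        miss_config = replace(
            make_config(scenario, strength, proportion), alpha0=cal_alpha0
        )
        incomplete = impose_missingness(trial, miss_config, seed=s_miss)

        if method == "cca":
            analysed = complete_case(incomplete)
            fit = fit_msm(replicate_and_weight(analysed))
            beta, theta = fit.beta, theta_from_beta(fit).theta
            if config.bootstrap_B > 0:
                bs = bootstrap_se(
                    incomplete, "cca", B=config.bootstrap_B, seed=s_boot
                )
                ses = np.concatenate([bs["beta_se"], bs["theta_se"]])
            else:
                ses = nan7
            t_df = None
        elif method == "mi":
            m = config.mi_m if config.mi_m is not None else default_m(proportion)
            spec = ImputationSpec(
                m=m,
                iterations=config.mi_iterations,
                seed=int(s_handle.generate_state(1)[0] % (2**31 - 1)),
            )
            completed = mice_impute(incomplete, spec)
            betas, beta_vars, theta_vars = [], [], []
            for d in completed:
                rep_data = replicate_and_weight(d)
                f = fit_msm(rep_data)
                betas.append(f.beta)
                cov = cluster_robust_cov(rep_data, f.beta)
                beta_vars.append(np.diag(cov))
                theta_vars.append(np.diag(CONTRAST_MATRIX @ cov @ CONTRAST_MATRIX.T))
            betas = np.array(betas)
            beta = betas.mean(axis=0)
            theta = CONTRAST_MATRIX @ beta
            if config.mi_mode == "rubin":
                pooled = pool_rubin(
                    np.hstack([betas, betas @ CONTRAST_MATRIX.T]),
                    np.hstack([beta_vars, theta_vars]),
                    df_complete=config.n_participants - 3,
                )
                ses = np.array([np.sqrt(p.total_var) for p in pooled])
                t_df = np.array([p.df for p in pooled])
            elif config.bootstrap_B > 0:
                bs = bootstrap_se(
                    incomplete,
                    "mi",
                    B=config.bootstrap_B,
                    seed=s_boot,
                    mi_m=config.mi_bootstrap_m,
                    mi_iterations=config.mi_iterations,
                )
                ses = np.concatenate([bs["beta_se"], bs["theta_se"]])
                t_df = None
            else:
                ses, t_df = nan7, None
        else:
            raise SmartmissError(f"unknown method {method!r}")
        return np.concatenate([beta, theta]), ses, t_df, None
    except Exception as exc:
        return nan7, nan7, None, f"replicate {rep} (spawn_key=({_cell_index(cell)}, {rep})): {exc}"


def run_cell(
    config: ExperimentConfig,
    cell: tuple,
    calibration_cache: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one grid cell; returns (per-replicate estimates, performance summary).

    ``cell`` is (scenario, proportion, strength, method).  The calibrated
    intercept is computed on demand and cached by (scenario, strength,
    proportion, delta) so both methods in a cell pair share identical
    missingness mechanisms.
    """
    scenario, proportion, strength, method = cell
    cal_key = (scenario, strength, proportion, config.delta)
    if calibration_cache is not None and cal_key in calibration_cache:
        alpha0 = calibration_cache[cal_key]
    else:
        alpha0 = calibrate_intercept(
            scenario, strength, proportion, config.delta, config.calibration_n
        )
        if calibration_cache is not None:
            calibration_cache[cal_key] = alpha0

    reps = range(config.n_replicates)
    if config.workers > 1:
        results = Parallel(n_jobs=config.workers)(
            delayed(_one_replicate)(config, cell, alpha0, r) for r in reps
        )
    else:
        results = [_one_replicate(config, cell, alpha0, r) for r in reps]

    errors = [e for *_, e in results if e is not None]
    if len(errors) > 0.01 * config.n_replicates:
        raise SmartmissError(
            f"cell {_cell_key(cell)}: {len(errors)}/{config.n_replicates} replicates "
            f"failed; first errors: {errors[:3]}"
        )

    ok = [r for r in results if r[3] is None]
    est = np.array([r[0] for r in ok])
    ses = np.array([r[1] for r in ok])
    t_df = None
    if ok and ok[0][2] is not None:
        t_df = np.array([r[2] for r in ok])

    est_df = pd.DataFrame(est, columns=PARAMETER_NAMES)
    est_df.insert(0, "replicate", [i for i, r in enumerate(results) if r[3] is None])
    ses_df = pd.DataFrame(ses, columns=[f"se_{p}" for p in PARAMETER_NAMES])
    per_replicate = pd.concat([est_df, ses_df], axis=1)

    summary = summarize(est, ses, analytic_truth(config.delta), t_df=t_df)
    for col, val in zip(
        ("scenario", "proportion", "strength", "method", "n_failed"),
        (scenario, proportion, strength, method, len(errors)),
    ):
        summary.insert(0, col, val)
    return per_replicate, summary


def run_experiment(config: ExperimentConfig, outdir) -> pd.DataFrame:
    """Run the configured grid and write tidy results to ``outdir``.

    Writes ``results.csv`` (one row per cell x parameter), per-cell
    estimate tables under ``cells/``, the config snapshot, the calibration
    cache, and a manifest with the config hash and per-cell wall times.
    Returns the tidy results table.
    """
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    cache: dict = {}
    summaries = []
    manifest = {"config_hash": _config_hash(config), "cells": {}}
    for cell in config.grid():
        t0 = time.time()
        per_rep, summary = run_cell(config, cell, cache)
        per_rep.to_csv(outdir / "cells" / f"{_cell_key(cell)}_estimates.csv", index=False)
        summaries.append(summary)
        manifest["cells"][_cell_key(cell)] = {"wall_s": round(time.time() - t0, 2)}
    results = pd.concat(summaries, ignore_index=True)
    results.to_csv(outdir / "results.csv", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        # round-trip through JSON so tuples serialise as plain lists
        yaml.safe_dump(json.loads(json.dumps(asdict(config))), fh, sort_keys=False)
    with open(outdir / "calibration.yaml", "w") as fh:
        yaml.safe_dump(
            {str(k): float(v) for k, v in cache.items()}, fh, sort_keys=True
        )
    from . import __version__

    manifest["version"] = __version__
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results


def _config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
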