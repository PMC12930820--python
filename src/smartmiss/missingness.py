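"""Calibrated missingness mechanisms for the simulated SMART.

Four scenarios, each defined by a logistic model on fully observed or
partially observed trial variables, with a monotone-dropout structure:
once the intermediate outcome ``O2`` is missing, the stage-2 treatment
``A2`` and the outcome ``Y`` are missing too, and once ``A2`` is missing
``Y`` is missing.  ``O1`` and ``A1`` are always observed.

Scenario 1 (MCAR): ``logit P(M_Y = 1) = alpha0``.
Scenario 2 (MAR given observed): ``logit P(M_Y = 1) = alpha0 + alpha1*O2
+ alpha2*I[A2 = 1]``; the ``A2`` indicator contributes 0 for responders,
who have no stage-2 randomisation.
Scenario 3 (dropout after stage 1): ``logit P(M_O2 = 1) = alpha0 +
alpha1*O1 + alpha2*I[A1 = 1]``; ``A2`` and ``Y`` are erased wherever
``O2`` is.
Scenario 4 (dropout before stage 2): ``logit P(M_A2 = 1) = alpha0 +
alpha1*O2``, evaluated for every participant; ``Y`` is erased wherever
the event fires, and for responders (who have no ``A2``) the event
erases ``Y`` only.

Slopes are ``log(OR)`` with OR 1.6 ("weak") or 3.0 ("strong").  The
intercept ``alpha0`` is calibrated by root-finding so the marginal
proportion of the scenario's driving indicator hits the target (0.2 or
0.4); calibration holds one large frozen simulated dataset fixed and
solves for the mean model probability on it, which is monotone and
noise-free in ``alpha0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import CalibrationError, ParameterError
from .simulate import SimulationParams, generate_trial

#: Odds ratios encoding association strength between predictors and dropout.
STRENGTH_OR = {"weak": 1.6, "strong": 3.0}

#: The indicator whose marginal proportion is calibrated, per scenario.
DRIVING_INDICATOR = {1: "M_Y", 2: "M_Y", 3: "M_O2", 4: "M_A2"}

MISSINGNESS_COLUMNS = ["M_O2", "M_A2", "M_Y"]


@dataclass(frozen=True)
class MissingnessConfig:
    """One calibrated missingness mechanism.

    ``alpha1``/``alpha2`` are log-odds slopes (both ``log(OR)`` where the
    scenario's model has the corresponding term, else 0).  ``alpha0`` is
    None until calibrated.  ``scenario4_nonresponders_only`` restricts the
    scenario-4 model to non-responders instead of evaluating it for the
    whole sample (the default evaluates it for everyone; for responders
    the event erases Y only).
    """

    scenario: int
    target_proportion: float
    strength: str
    alpha0: float | None = None
    alpha1: float = 0.0
    alpha2: float = 0.0
    scenario4_nonresponders_only: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4):
            raise ParameterError(f"scenario must be in 1..4, got {self.scenario!r}")
        if not (0.0 < self.target_proportion < 1.0):
            raise ParameterError(
                f"target_proportion must be in (0, 1), got {self.target_proportion!r}"
            )
        if self.strength not in STRENGTH_OR:
            raise ParameterError(
                f"strength must be one of {sorted(STRENGTH_OR)}, got {self.strength!r}"
            )

    @property
    def driving_indicator(self) -> str:
        return DRIVING_INDICATOR[self.scenario]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MissingnessConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def make_config(
    scenario: int, strength: str, target_proportion: float
) -> MissingnessConfig:
    """Build an uncalibrated config with the scenario's slope pattern."""
    lo = math.log(STRENGTH_OR[strength])
    if scenario == 1:
        a1, a2 = 0.0, 0.0
    elif scenario in (2, 3):
        a1, a2 = lo, lo
    else:  # scenario 4: single O2 slope
        a1, a2 = lo, 0.0
    return MissingnessConfig(
        scenario=scenario,
        target_proportion=target_proportion,
        strength=strength,
        alpha1=a1,
        alpha2=a2,
    )


def _linear_predictor(trial: pd.DataFrame, config: MissingnessConfig) -> np.ndarray:
    """Covariate part (no intercept) of the scenario's logistic model."""
    s = config.scenario
    if s == 1:
        return np.zeros(len(trial))
    if s == 2:
        a2_ind = np.where(trial["A2"].to_numpy() == 1.0, 1.0, 0.0)  # 0 for responders
        return config.alpha1 * trial["O2"].to_numpy() + config.alpha2 * a2_ind
    if s == 3:
        a1_ind = (trial["A1"].to_numpy() == 1.0).astype(float)
        return config.alpha1 * trial["O1"].to_numpy() + config.alpha2 * a1_ind
    # scenario 4
    return config.alpha1 * trial["O2"].to_numpy()


def calibrate_intercept(
    scenario: int,
    strength: str,
    target_proportion: float,
    delta: float = 0.1,
    calibration_n: int = 1_000_000,
    seed: int = 20_210_000,
) -> float:
    """Find alpha0 achieving the target marginal missingness proportion.

    Scenario 1 has no covariates, so ``alpha0 = logit(target)`` exactly.
    Otherwise one frozen dataset of ``calibration_n`` participants is
    generated and ``mean(expit(alpha0 + lp))`` — the expected proportion
    of the driving indicator given the frozen covariates — is solved for
    the target by Brent root-finding, widening the bracket if needed.
    """
    config = make_config(scenario, strength, target_proportion)
    if scenario == 1:
        return float(logit(target_proportion))

    trial = generate_trial(SimulationParams(calibration_n, delta, seed))
    if scenario == 4 and config.scenario4_nonresponders_only:
        trial = trial[trial["R"] == 0]
    lp = _linear_predictor(trial, config)

    def gap(a0: float) -> float:
        return float(np.mean(expit(a0 + lp))) - target_proportion

    lo, hi = -10.0, 10.0
    for _ in range(8):
        if gap(lo) < 0.0 < gap(hi):
            return float(brentq(gap, lo, hi, xtol=1e-10))
        lo *= 2.0
        hi *= 2.0
    raise CalibrationError(
        f"could not bracket alpha0 for scenario {scenario}, strength {strength}, "
        f"target {target_proportion}"
    )


def calibrated_config(
    scenario: int,
    strength: str,
    target_proportion: float,
    delta: float = 0.1,
    calibration_n: int = 1_000_000,
    seed: int = 20_210_000,
) -> MissingnessConfig:
    """Convenience: build a config and calibrate its intercept in one step."""
    config = make_config(scenario, strength, target_proportion)
    alpha0 = calibrate_intercept(
        scenario, strength, target_proportion, delta, calibration_n, seed
    )
    return replace(config, alpha0=alpha0)


def impose_missingness(
    trial: pd.DataFrame, config: MissingnessConfig, seed: int
) -> pd.DataFrame:
    """Apply the calibrated mechanism to a complete trial dataset.

    Returns a copy with indicator columns ``M_O2, M_A2, M_Y`` and the
    corresponding values blanked to NaN.  ``R`` is blanked alongside
    ``O2`` since responder status is a deterministic function of ``O2``.
    Monotone-dropout invariants hold on the output.
    """
    if config.alpha0 is None:
        raise ParameterError("config must be calibrated (alpha0 is None)")
    s = config.scenario
    rng = np.random.default_rng(seed)
    n = len(trial)
    out = trial.copy()
    m_o2 = np.zeros(n, dtype=int)
    m_a2 = np.zeros(n, dtype=int)
    m_y = np.zeros(n, dtype=int)

    p = expit(config.alpha0 + _linear_predictor(trial, config))
    draw = rng.random(n) < p

    if s in (1, 2):
        m_y = draw.astype(int)
    elif s == 3:
        m_o2 = draw.astype(int)
        m_a2 = m_o2.copy()
        m_y = m_o2.copy()
    else:  # scenario 4
        if config.scenario4_nonresponders_only:
            draw &= trial["R"].to_numpy() == 0
        m_a2 = draw.astype(int)
        m_y = m_a2.copy()

    out["M_O2"] = m_o2
    out["M_A2"] = m_a2
    out["M_Y"] = m_y
    out.loc[out["M_O2"] == 1, ["O2", "R"]] = np.nan
    out.loc[out["M_A2"] == 1, "A2"] = np.nan
    out.loc[out["M_Y"] == 1, "Y"] = np.nan
    _assert_monotone(out)
    return out


def _assert_monotone(incomplete: pd.DataFrame) -> None:
    m_o2 = incomplete["M_O2"].to_numpy()
    m_a2 = incomplete["M_A2"].to_numpy()
    m_y = incomplete["M_Y"].to_numpy()
    if np.any(m_o2 > m_a2) or np.any(m_o2 > m_y) or np.any(m_a2 > m_y):
        raise AssertionError("monotone dropout invariant violated")
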