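"""Two-stage SMART data generation and truth values for the DTR means.

The trial has two treatment stages.  Every participant is randomised at
stage 1 to ``A1`` in {-1, +1} with probability 0.5.  An intermediate
outcome ``O2`` is observed; participants with ``O2 > 0`` are
*non-responders* and are re-randomised to ``A2`` in {-1, +1} (again with
probability 0.5), while responders (``O2 <= 0``) continue on their stage-1
treatment and have no ``A2``.  The continuous final outcome is

    Y = 1 + O1 + O2 + A1*(delta + O1) + I(O2 > 0)*(delta/2)*A2 + eps

with ``O1 ~ N(0, 1)``, ``O2 ~ N(0.5*O1 + 0.5*I(A1 = -1), 1)`` and
``eps ~ N(0, 1)``.  ``delta`` is the treatment-effect magnitude at both
stages (0.1 by default throughout the package).

The four embedded DTRs are the (A1, A2) rules (+1,+1), (+1,-1), (-1,+1),
(-1,-1); a responder's A2 entry is vacuous for them.  The marginal
structural model (MSM) ``E[Y(d)] = beta0 + beta1*A1 + beta2*A2`` projects
the four regimen means onto three coefficients, and the DTR means are the
contrasts ``theta = C @ beta`` with C the +/-1 design matrix of the four
rules.  :func:`analytic_truth` gives the exact projection truth in closed
form; :func:`monte_carlo_truth` recovers it by running the full IPW
estimation pipeline on freshly simulated complete data.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ParameterError

#: Columns of a trial dataset, in canonical order.
TRIAL_COLUMNS = ["id", "O1", "A1", "O2", "R", "A2", "Y"]

#: Design randomisation probabilities; weights are derived as 1/p products.
P_STAGE1 = 0.5
P_STAGE2 = 0.5


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated trial dataset.

    Parameters
    ----------
    n_participants
        Number of participants (rows) to generate.
    delta
        Treatment-effect magnitude at both stages.
    seed
        Seed for the dataset's own RNG stream.
    """

    n_participants: int
    delta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_participants, (int, np.integer)) and self.n_participants >= 1):
            raise ParameterError(
                f"n_participants must be a positive integer, got {self.n_participants!r}"
            )
        if not math.isfinite(self.delta):
            raise ParameterError(f"delta must be finite, got {self.delta!r}")


#: 4x3 contrast matrix mapping MSM coefficients to the four DTR means.
#: Rows are DTR1..DTR4 = (A1, A2) rules (+1,+1), (+1,-1), (-1,+1), (-1,-1).
CONTRAST_MATRIX = np.array(
    [[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]], dtype=float
)


@dataclass(frozen=True)
class TruthValues:
    """True MSM coefficients and DTR means, with provenance tag."""

    beta: np.ndarray
    theta: np.ndarray
    method: str  # "analytic" or "monte_carlo"
    beta_mcse: np.ndarray | None = None
    theta_mcse: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))

    def as_vector(self) -> np.ndarray:
        """Concatenated (beta0, beta1, beta2, theta1..theta4)."""
        return np.concatenate([self.beta, self.theta])


#: Parameter names matching :meth:`TruthValues.as_vector` order.
PARAMETER_NAMES = ["beta0", "beta1", "beta2", "theta1", "theta2", "theta3", "theta4"]


def generate_trial(params: SimulationParams) -> pd.DataFrame:
    """Simulate one complete SMART dataset.

    Responder status is ``R = I(O2 <= 0)``; the measure-zero tie ``O2 = 0``
    is classified as responder.  ``A2`` is NaN for responders: it is a
    structural not-applicable marker, not a missing value.

    Returns a DataFrame with columns ``id, O1, A1, O2, R, A2, Y``.
    """
    n = params.n_participants
    delta = params.delta
    rng = np.random.default_rng(params.seed)

    o1 = rng.standard_normal(n)
    a1 = np.where(rng.random(n) < P_STAGE1, 1.0, -1.0)
    o2 = rng.normal(0.5 * o1 + 0.5 * (a1 == -1), 1.0)
    r = (o2 <= 0).astype(int)
    # Draw A2 for everyone from one stream position, then blank responders:
    # keeps the stream layout independent of the realised responder pattern.
    a2_all = np.where(rng.random(n) < P_STAGE2, 1.0, -1.0)
    a2 = np.where(r == 0, a2_all, np.nan)
    s = (o2 > 0).astype(float)
    y = (
        1.0
        + o1
        + o2
        + a1 * (delta + o1)
        + s * (delta / 2.0) * np.where(r == 0, a2, 0.0)
        + rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "O1": o1,
            "A1": a1,
            "O2": o2,
            "R": r,
            "A2": a2,
            "Y": y,
        }
    )


def _cell_means(delta: float) -> np.ndarray:
    """Exact E[Y(a1, a2)] for the four DTRs, order DTR1..DTR4.

    Under rule (a1, a2): E[O1] = 0, E[O2] = mu(a1) = 0.5*I(a1 = -1), the
    A1*O1 term is mean-zero, and the stage-2 term applies only to
    non-responders, contributing (delta/2)*a2*P(O2 > 0 | a1).  Marginally
    O2 | a1 ~ N(mu(a1), 1.25) (the O1 contribution adds 0.25 to the unit
    conditional variance), so P(O2 > 0 | a1) = Phi(mu(a1)/sqrt(1.25)).
    """
    means = []
    for a1, a2 in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
        mu = 0.5 * (a1 == -1)
        p_nonresp = norm.cdf(mu / np.sqrt(1.25))
        means.append(1.0 + mu + delta * a1 + (delta / 2.0) * a2 * p_nonresp)
    return np.array(means)


def analytic_truth(delta: float = 0.1) -> TruthValues:
    """Closed-form projection truth for the MSM coefficients and DTR means.

    The MSM has no A1*A2 interaction, so beta is the least-squares
    projection of the four regimen means onto (1, A1, A2).  Replication
    and design weighting give every (A1, A2) cell equal total weight, so
    the projection is the orthogonal-contrast one:

        beta0 = mean of the four cell means
        beta1 = (m11 + m1,-1 - m-1,1 - m-1,-1) / 4
        beta2 = (m11 - m1,-1 + m-1,1 - m-1,-1) / 4

    and ``theta = C @ beta`` drops the (small) interaction component.
    """
    if not math.isfinite(delta):
        raise ParameterError(f"delta must be finite, got {delta!r}")
    m = _cell_means(delta)
    beta = np.array(
        [
            m.mean(),
            (m[0] + m[1] - m[2] - m[3]) / 4.0,
            (m[0] - m[1] + m[2] - m[3]) / 4.0,
        ]
    )
    return TruthValues(beta=beta, theta=CONTRAST_MATRIX @ beta, method="analytic")


def monte_carlo_truth(
    n_datasets: int,
    n_per_dataset: int,
    delta: float = 0.1,
    seed: int = 0,
) -> TruthValues:
    """Simulation-based truth: average the IPW estimates over complete data.

    Generates ``n_datasets`` complete trials of ``n_per_dataset``
    participants, runs the replication-and-weighting estimator on each,
    and averages the coefficient estimates.  Each dataset gets its own
    RNG stream derived from ``(seed, replicate index)``.
    """
    if n_datasets < 1 or n_per_dataset < 1:
        raise ParameterError("n_datasets and n_per_dataset must be >= 1")
    from .estimator import fit_msm, replicate_and_weight  # deferred: circular import

    ss = np.random.SeedSequence(seed)
    betas = np.empty((n_datasets, 3))
    for i in range(n_datasets):
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i,))
        params = SimulationParams(n_per_dataset, delta, seed=child)
        try:
            trial = _generate_with_seedseq(params)
            fit = fit_msm(replicate_and_weight(trial))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"estimator failed on truth replicate {i} (spawn_key=({i},), entropy={ss.entropy})"
            ) from exc
        betas[i] = fit.beta
    thetas = betas @ CONTRAST_MATRIX.T
    beta_mean = betas.mean(axis=0)
    return TruthValues(
        beta=beta_mean,
        theta=CONTRAST_MATRIX @ beta_mean,
        method="monte_carlo",
        beta_mcse=betas.std(axis=0, ddof=1) / np.sqrt(n_datasets),
        theta_mcse=thetas.std(axis=0, ddof=1) / np.sqrt(n_datasets),
    )


def _generate_with_seedseq(params: SimulationParams) -> pd.DataFrame:
    """generate_trial accepting a SeedSequence smuggled through params.seed."""
    return generate_trial(params)


def write_trial_csv(trial: pd.DataFrame, path_or_buf) -> None:
    """Write a (complete or incomplete) trial table to CSV.

    Not-applicable and missing values are written as empty fields; the
    header is mandatory.  Round-trips losslessly with
    :func:`read_trial_csv`.
    """
    trial.to_csv(path_or_buf, index=False, na_rep="")


def read_trial_csv(path_or_buf) -> pd.DataFrame:
    """Read a trial CSV written by :func:`write_trial_csv`.

    Validates the schema and the -1/+1 treatment coding; 0/1-coded
    treatments are rejected rather than silently recoded.
    """
    df = pd.read_csv(path_or_buf)
    missing_cols = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParameterError(f"trial CSV missing required columns: {missing_cols}")
    for col in ("A1", "A2"):
        vals = df[col].dropna().unique()
        if not np.all(np.isin(vals, [-1.0, 1.0])):
            raise ParameterError(
                f"column {col} must be coded -1/+1; found values {sorted(vals)}"
            )
    if df["id"].duplicated().any():
        raise ParameterError("participant ids must be unique")
    return df
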