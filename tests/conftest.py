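import numpy as np
import pandas as pd
import pytest

import smartmiss as sm


@pytest.fixture(scope="session")
def small_trial() -> pd.DataFrame:
    """A 400-participant complete trial used across tests."""
    return sm.generate_trial(sm.SimulationParams(400, 0.1, seed=20260901))


@pytest.fixture
def toy_trial() -> pd.DataFrame:
    """One responder and one non-responder, hand-written."""
    return pd.DataFrame(
        {
            "id": [0, 1],
            "O1": [0.3, -0.2],
            "A1": [1.0, -1.0],
            "O2": [-0.5, 0.8],
            "R": [1, 0],
            "A2": [np.nan, 1.0],
            "Y": [1.1, 2.4],
        }
    )


@pytest.fixture(scope="session")
def scenario3_incomplete(small_trial) -> pd.DataFrame:
    """Scenario-3 (dropout after stage 1) missingness at 40%, OR 3."""
    from smartmiss.missingness import calibrated_config, impose_missingness

    cfg = calibrated_config(3, "strong", 0.4, calibration_n=200_000)
    return impose_missingness(small_trial, cfg, seed=77)
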