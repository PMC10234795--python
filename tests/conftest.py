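import numpy as np
import pandas as pd
import pytest

from move24.epochs import EpochSeries
from move24.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants with full epoch signal (shared across tests)."""
    cfg = SimulationConfig(n_participants=6, n_schools=3, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def regression_cohort():
    """300 participants without epoch signal, for model-recovery tests."""
    cfg = SimulationConfig(n_participants=300, n_schools=10, seed=7)
    return simulate_cohort(cfg, generate_signal=False)


def make_series(enmo, z_angle=None, start="2022-09-05", epoch_seconds=5,
                pid="T01"):
    enmo = np.asarray(enmo, dtype=float)
    if z_angle is None:
        z_angle = np.zeros_like(enmo)
    return EpochSeries(pid, pd.Timestamp(start), epoch_seconds, enmo, z_angle)


@pytest.fixture
def flat_week():
    """Seven complete days of constant 50 mg."""
    n = 7 * 86400 // 5
    return make_series(np.full(n, 50.0))
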