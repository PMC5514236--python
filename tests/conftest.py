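import numpy as np
import pytest

import mbaod
from mbaod import scenario


@pytest.fixture(scope="session")
def theta_true():
    return scenario.true_parameters()


@pytest.fixture(scope="session")
def theta_guess():
    return scenario.initial_guess()


@pytest.fixture(scope="session")
def sparse_design():
    return scenario.initial_design("sparse")


@pytest.fixture(scope="session")
def rich_design():
    return scenario.initial_design("rich")


@pytest.fixture(scope="session")
def small_dataset(theta_true, sparse_design):
    """One simulated first cohort (8 subjects, sparse schedule)."""
    return mbaod.simulate_dataset(sparse_design, theta_true, seed=42)


@pytest.fixture(scope="session")
def mini_histories():
    """Three small lnD replicates shared by bookkeeping/summary tests."""
    from mbaod.config import default_config

    cfg = default_config(max_cohorts=4, n_stop_sim=1000, seed=7)
    return [mbaod.run_mbaod(cfg, replicate=r) for r in range(3)]


@pytest.fixture(autouse=True)
def _quiet_numerics():
    """Optimizer exploration legitimately visits overflow regions."""
    with np.errstate(over="ignore", invalid="ignore"):
        yield
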