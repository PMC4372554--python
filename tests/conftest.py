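"""Shared fixtures: the captive-study inputs and reduced MCMC budgets."""

import numpy as np
import pytest

from tdfmix import MCMCConfig
from tdfmix.datasets import (
    CAPTIVE_SOURCES,
    DIET_ALPHA,
    FOX_TDF,
    WOLF_RUMP_MEAN,
    WOLF_RUMP_SD,
    WOLF_TDF,
)
from tdfmix.synthetic import simulate_consumers


@pytest.fixture(scope="session")
def captive_sources():
    return CAPTIVE_SOURCES


@pytest.fixture(scope="session")
def diet_alpha():
    return DIET_ALPHA


@pytest.fixture(scope="session")
def fox_tdf():
    return FOX_TDF


@pytest.fixture(scope="session")
def wolf_tdf():
    return WOLF_TDF


@pytest.fixture
def wolf_consumers():
    """10 consumers simulated from the wolf rump hair summary statistics."""

    def make(seed: int = 1, n: int = 10):
        return simulate_consumers(WOLF_RUMP_MEAN, WOLF_RUMP_SD, n, seed=seed)

    return make


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced chain budget for unit tests; still comfortably converged for
    this low-dimensional posterior (PSRF is asserted where it matters)."""
    return MCMCConfig(burn_in=1500, n_samples=1000, thin=1, psrf_action="ignore")


@pytest.fixture(scope="session")
def medium_mcmc():
    """Budget used for quantitative posterior checks (PSRF < 1.1 enforced
    by the tests that rely on it)."""
    return MCMCConfig(burn_in=8000, n_samples=3000, thin=3, psrf_action="warn")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
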