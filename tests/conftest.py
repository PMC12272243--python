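import numpy as np
import pytest

from oscnets.dynemo import DynemoConfig, fit_dynemo
from oscnets.hmm import fit_hmm
from oscnets.prep import PrepConfig, prepare
from oscnets.simulate import SimulationConfig, simulate_parcels


@pytest.fixture(scope="session")
def small_sim():
    """A short default-style simulation for cheap unit tests."""
    return simulate_parcels(SimulationConfig(n_samples=6000, seed=123))


@pytest.fixture(scope="session")
def small_prepped(small_sim):
    data, _ = small_sim
    return prepare(data, PrepConfig(n_lags=2, n_components=120, standardise=True))


@pytest.fixture(scope="session")
def full_sim():
    """The default simulation at full scale (25600 samples, 38 parcels)."""
    return simulate_parcels(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def full_prepped(full_sim):
    data, _ = full_sim
    return prepare(data, PrepConfig(n_lags=2, n_components=120, standardise=True))


@pytest.fixture(scope="session")
def dynemo_full(full_prepped):
    """Full-scale DyNeMo fit (3 modes, best of 10 seeded initialisations)."""
    return fit_dynemo(
        full_prepped, 3, DynemoConfig(max_epochs=16, n_init=10), seed=1
    )


@pytest.fixture(scope="session")
def hmm_full(full_prepped):
    """Full-scale TDE-HMM fit (3 states, best of 10 seeded initialisations)."""
    return fit_hmm(full_prepped, 3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
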