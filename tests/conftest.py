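import numpy as np
import pytest

from triphase import SimConfig, fit_simulated
from triphase.simdata import simulate_experiment


@pytest.fixture(scope="session")
def noiseless_cfg():
    """One noiseless tiller at the reference-experiment truth values."""
    return SimConfig(noise_sd_ler=0.0, n_replicates=1)


@pytest.fixture(scope="session")
def noiseless_experiment(noiseless_cfg):
    return simulate_experiment(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_cfg):
    return fit_simulated(noiseless_cfg)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
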