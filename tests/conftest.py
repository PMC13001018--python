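import numpy as np
import pandas as pd
import pytest

from oakselect.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced single-seed experiment used by several test modules."""
    cfg = SimConfig(seed=11, n_families=8, n_per_family=5,
                    spectral_noise_sd=0.001)
    return simulate_experiment(cfg, with_spectra=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def balanced_family_data(rng):
    """Balanced one-way family data: 20 families x 10, V_g=0.3, V_e=0.7."""
    fam = np.repeat(np.arange(20), 10)
    u = rng.normal(0, np.sqrt(0.3), 20)
    y = u[fam] + rng.normal(0, np.sqrt(0.7), 200)
    return y, fam
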