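import numpy as np
import pytest

from larchbiomass import SimulationConfig, simulate_stand


@pytest.fixture(scope="session")
def default_stand():
    """One default-sized simulated stand shared across read-only tests."""
    config = SimulationConfig(seed=1234)
    trees, taper, biomass = simulate_stand(config)
    return config, trees, taper, biomass


@pytest.fixture()
def small_stand():
    """A 30-tree stand, regenerated per test (cheap, mutable)."""
    config = SimulationConfig(n_trees=30, seed=99)
    trees, taper, biomass = simulate_stand(config)
    return config, trees, taper, biomass


@pytest.fixture()
def noiseless_stand():
    """Zero-noise stand: every downstream fit should be exact."""
    config = SimulationConfig(
        n_trees=30, seed=7, taper_noise_sd=0.0, biomass_cv=(0.0, 0.0, 0.0),
        error_corr=np.eye(3),
    )
    trees, taper, biomass = simulate_stand(config)
    return config, trees, taper, biomass
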