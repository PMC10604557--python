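import numpy as np
import pytest

import specfinger as sf


@pytest.fixture(scope="session")
def profiles():
    return sf.default_class_profiles()


@pytest.fixture(scope="session")
def sim_config():
    return sf.SimulationConfig(n_per_class=50, seed=1)


@pytest.fixture(scope="session")
def cohort(profiles, sim_config):
    """50 FM + 50 LC spectra at the default study conditions."""
    return sf.simulate_cohort([profiles["FM"], profiles["LC"]], sim_config)


@pytest.fixture(scope="session")
def noise_free_fm(profiles, sim_config):
    """Deterministic FM construction (all stochastic terms off)."""
    sp, truth = sf.render_spectrum(
        profiles["FM"].noise_free(), sim_config, np.random.default_rng(0), "FM_clean"
    )
    return sp, truth


@pytest.fixture(scope="session")
def noise_free_lc(profiles, sim_config):
    sp, truth = sf.render_spectrum(
        profiles["LC"].noise_free(), sim_config, np.random.default_rng(0), "LC_clean"
    )
    return sp, truth


@pytest.fixture(scope="session")
def tiny_cohort(profiles):
    """4 + 4 samples for fast oracle-equivalence checks."""
    cfg = sf.SimulationConfig(n_per_class=4, seed=7)
    return sf.simulate_cohort([profiles["FM"], profiles["LC"]], cfg)
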