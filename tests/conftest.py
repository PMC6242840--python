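import numpy as np
import pytest

from pomstoich import synthetic as syn


@pytest.fixture(scope="session")
def small_cruise():
    """A modest noiseless cruise shared by read-only tests."""
    cfg = syn.CruiseConfig(n_stations=60, noise_cv=0.0, seed=11)
    samples, truth = syn.generate_transect(cfg)
    profiles = syn.generate_profiles(cfg)
    return cfg, samples, truth, profiles


@pytest.fixture(scope="session")
def noisy_cruise():
    """Default-condition cruise with triplicate noise."""
    cfg = syn.CruiseConfig(seed=7)
    samples, truth = syn.generate_transect(cfg)
    profiles = syn.generate_profiles(cfg)
    return cfg, samples, truth, profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
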