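import numpy as np
import pytest

from nacloop import SimulationConfig, VENTRAL_ROLES, clean, simulate


@pytest.fixture(scope="session")
def buffet_small():
    """One short buffet session on the ventral channels (seed 0)."""
    config = SimulationConfig.buffet(duration_s=600.0, rng_seed=0, channels=VENTRAL_ROLES)
    rec, log = simulate(config)
    return config, rec, log


@pytest.fixture(scope="session")
def buffet_small_clean(buffet_small):
    config, rec, log = buffet_small
    return config, clean(rec), log


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
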