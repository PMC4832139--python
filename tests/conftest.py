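import numpy as np
import pytest

import psykernel as pk


@pytest.fixture(scope="session")
def default_config():
    return pk.SceneConfig()


@pytest.fixture(scope="session")
def small_log(default_config):
    """A 40-trial session with tracks (used by several modules)."""
    return pk.run_session(default_config, 40, seed=7)


@pytest.fixture(scope="session")
def big_log(default_config):
    """A 2000-trial session without tracks (statistical checks)."""
    return pk.run_session(default_config, 2000, seed=11, record_tracks=False)


@pytest.fixture(scope="session")
def express_session(small_log):
    """Observer that always expresses (latencies clear of class borders)."""
    obs = pk.ObserverConfig(steepness=500.0,
                            kernel_cov=((1e-6, 0.0), (0.0, 1e-6)),
                            p_express=1.0, p_regular=0.0, p_press=0.0,
                            express_latency_range=(40.0, 115.0))
    trace, log = pk.simulate_responses(small_log, obs, seed=21)
    return obs, trace, log


@pytest.fixture
def rng():
    return np.random.default_rng(0)
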