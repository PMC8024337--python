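import functools

import numpy as np
import pytest

from cytosim.scenarios import preset, run_ensemble

ENSEMBLE_N = 20
ENSEMBLE_SEED = 1


@functools.lru_cache(maxsize=None)
def get_ensemble(name: str):
    """Session-wide cached 20-run ensemble for a named preset (seeds 1..20)."""
    return run_ensemble(preset(name), ENSEMBLE_N, ENSEMBLE_SEED)


@pytest.fixture(scope="session")
def control_ens():
    return get_ensemble("control")


@pytest.fixture(scope="session")
def wnt8a_oe_ens():
    return get_ensemble("wnt8a_oe")


@pytest.fixture(scope="session")
def vangl2_longer_ens():
    return get_ensemble("vangl2_longer")


@pytest.fixture(scope="session")
def wnt8a_vangl2_ens():
    return get_ensemble("wnt8a_vangl2")


@pytest.fixture(scope="session")
def rescue_ens():
    return get_ensemble("rescue_fewer")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
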