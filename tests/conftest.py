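import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rascal import synth
from rascal.structio import Selection

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted():
    """Planted complex with (3 hbonds, 1 salt bridge, 5 nonbonded)."""
    return synth.make_planted_complex(3, 1, 5, seed=7)


@pytest.fixture(scope="session")
def kras_like():
    return synth.make_kras_like()


@pytest.fixture(scope="session")
def complex_like():
    return synth.make_complex_like()


@pytest.fixture(scope="session")
def slab():
    return synth.make_lipid_slab(60.0, 60.0, 5.0, headgroup_z=2.0, thickness=4.0)


@pytest.fixture
def chain_a():
    return Selection(chains=("A",))


@pytest.fixture
def chain_b():
    return Selection(chains=("B",))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
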