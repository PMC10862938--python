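import pytest

from ssediff import enumerate_range_states, GeoSSEParams, validate_params
from ssediff.state_space import required_split_keys


@pytest.fixture
def space2():
    return enumerate_range_states(["A", "B"])


@pytest.fixture
def space3():
    return enumerate_range_states(["A", "B", "C"])


def random_geosse_params(space, rng, low=0.0, high=1.0):
    """Random complete rate set with entries uniform in [low, high]."""
    u = lambda: float(rng.uniform(low, high))
    w = {r: u() for r in space.regions}
    e = {r: u() for r in space.regions}
    d = {
        (k, l): u()
        for k in space.regions
        for l in space.regions
        if k != l
    }
    b = {key: u() for key in required_split_keys(space)}
    return validate_params(GeoSSEParams(w=w, e=e, d=d, b=b), space)


@pytest.fixture
def make_random_params():
    return random_geosse_params


@pytest.fixture
def benchmark1_params(space2):
    from ssediff import FIXTURES

    _, params, _, _ = FIXTURES["two_region_benchmark1"].load()
    return params
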