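import pytest
from hypothesis import HealthCheck, settings

from pdznet.features import load_index_table
from pdznet.selectivity import build_all_spaces
from pdznet.synthetic import generate_world, world_pocket_vectors

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def index_table():
    return load_index_table()


@pytest.fixture(scope="session")
def world():
    """The reference synthetic study world (30 domains, 3 classes, 5% noise)."""
    return generate_world(seed=11)


@pytest.fixture(scope="session")
def world_vectors(world, index_table):
    return world_pocket_vectors(world, index_table)


@pytest.fixture(scope="session")
def spaces(world, world_vectors):
    return build_all_spaces(world.interactions, world_vectors)
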