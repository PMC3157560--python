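import pytest
from hypothesis import HealthCheck, settings

from forage3d import make_maze
from forage3d.pipeline import reproduce_controls

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pegboard():
    return make_maze("pegboard")


@pytest.fixture(scope="session")
def lattice():
    return make_maze("lattice")


@pytest.fixture(scope="session")
def pegboard_control():
    """Pooled optimised-control study on the pegboard: 80 seeded layouts
    with balanced start corners, GA at 20 restarts x 2000 generations."""
    return reproduce_controls("pegboard", n_trials=80, seed=1)


@pytest.fixture(scope="session")
def lattice_control():
    """Pooled optimised-control study on the lattice: 80 seeded layouts
    with balanced bottom/top starts, GA at 20 restarts x 2000 generations."""
    return reproduce_controls("lattice", n_trials=80, seed=1)
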