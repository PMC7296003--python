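import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tetramer():
    """Idealized six-stranded β-sheet tetramer fixture with ground truth."""
    from oligopore import synth

    return synth.make_tetramer_coords()


@pytest.fixture(scope="session")
def tetramer_structure(tetramer):
    return tetramer[0]


@pytest.fixture(scope="session")
def helix():
    from oligopore import synth

    return synth.make_helix_coords(16)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
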