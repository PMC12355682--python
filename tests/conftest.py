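import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qmmmkit import FixtureSpec, generate, make_junction_case

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def single_cut():
    """A 3-residue chain with one CA-CB junction."""
    return make_junction_case("single_cut", seed=0)


@pytest.fixture
def dipeptide():
    """Two neutral residues, no partition."""
    return generate(FixtureSpec(2, ("ALA", "ALA"), seed=0))


def rotate_translate(positions: np.ndarray, seed: int = 0) -> np.ndarray:
    """A random rigid motion (for invariance tests)."""
    rng = np.random.default_rng(seed)
    a, b, c = rng.uniform(0, 2 * np.pi, 3)
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rx = np.array([[1, 0, 0], [0, np.cos(c), -np.sin(c)], [0, np.sin(c), np.cos(c)]])
    return positions @ (rz @ ry @ rx).T + rng.uniform(-20, 20, 3)
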