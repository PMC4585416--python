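import numpy as np
import pytest

from shollroot import (
    Polyline,
    RootSystem,
    default_params,
    sample_root_system,
)


@pytest.fixture(scope="session")
def straight_system() -> RootSystem:
    """A 2.6 cm vertical primary with no laterals."""
    return RootSystem(Polyline([(0.0, 0.0), (0.0, 2.6)]))


@pytest.fixture(scope="session")
def branched_system() -> RootSystem:
    """Vertical primary plus one horizontal lateral branching at 0.5 cm."""
    lateral = Polyline([(0.0, 0.5), (1.2, 0.5)])
    return RootSystem(Polyline([(0.0, 0.0), (0.0, 2.6)]), ((0.5, lateral),))


@pytest.fixture(scope="session")
def dr_control_system():
    """One simulated drought-resistant control plant (fixed seed)."""
    return sample_root_system(default_params("DR", "control"), seed=42)


def random_polyline(rng: np.random.Generator, n_segments: int | None = None) -> Polyline:
    """Short random polyline spanning the unit-ish neighbourhood of the origin."""
    n = n_segments or rng.integers(2, 7)
    pts = np.cumsum(rng.uniform(-0.8, 0.8, size=(n + 1, 2)), axis=0)
    pts += rng.uniform(-1.5, 1.5, size=2)
    return Polyline(pts)
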