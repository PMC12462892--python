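import numpy as np
import pytest

from phl import GridComplex, ball, solid_torus, four_ball_model


def grid_about(half_extent, spacing, center=(0.0, 0.0, 0.0)):
    """Cube grid of the given half extent centred on ``center``."""
    n = int(np.ceil(2 * half_extent / spacing)) + 1
    half = (n - 1) * spacing / 2.0
    origin = tuple(c - half for c in center)
    return GridComplex((n, n, n), spacing, origin)


@pytest.fixture(scope="session")
def ball_grid():
    """Unit ball comfortably inside a 15^3 grid."""
    return grid_about(1.45, 0.2), ball(radius=1.0)


@pytest.fixture(scope="session")
def torus_grid():
    """Solid torus (R=2, r=0.6) inside a coarse grid."""
    return grid_about(3.1, 0.25), solid_torus()


@pytest.fixture(scope="session")
def four_ball_grid():
    """Four-ball tetrahedron model on a coarse grid (separate components)."""
    return grid_about(2.9, 0.25), four_ball_model()
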