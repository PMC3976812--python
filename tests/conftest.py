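import numpy as np
import pytest

from hetex.quantization import QuantizedVoi
from hetex.phantom import LesionSpec, PhantomSpec, make_phantom


def grid_to_qvoi(grid, L=None):
    """Build a QuantizedVoi from a dense 2D/3D level grid (0 = outside)."""
    grid = np.asarray(grid)
    if grid.ndim == 2:
        grid = grid[None]
    coords = np.argwhere(grid > 0)
    levels = grid[grid > 0]
    L = int(L or levels.max())
    return QuantizedVoi(coords, levels, L, 0.0, float(L))


def random_grid(rng, max_side=6, levels=3, fill=0.8, three_d=False):
    """Random small label grid with ~``fill`` in-VOI fraction."""
    if three_d:
        shape = tuple(rng.integers(2, max_side + 1, size=3))
    else:
        shape = (1, *rng.integers(2, max_side + 1, size=2))
    grid = rng.integers(1, levels + 1, size=shape)
    grid[rng.random(shape) > fill] = 0
    if (grid > 0).sum() < 2:
        grid.flat[:2] = [1, levels]
    return grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def uniform_phantom():
    spec = PhantomSpec(lesions=[LesionSpec((13, 12, 12), 18.0, 5.0)], seed=3)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def fragmented_phantom():
    spec = PhantomSpec(
        lesions=[LesionSpec((13, 12, 12), 18.0, 5.0, zones=12, level_spread=2.0)],
        noise_sd=0.01, seed=3)
    return make_phantom(spec)
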