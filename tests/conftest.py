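import numpy as np
import pytest

from mrhotspot import BinaryMask, Grid, PhantomSpec, ScalarMap


@pytest.fixture
def grid() -> Grid:
    return Grid((10, 10, 10), (3.4, 3.4, 3.4))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240943)


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A phantom small enough for per-test generation."""
    return PhantomSpec(shape=(24, 24, 20))


def make_map(grid: Grid, values, unit: str = "ratio") -> ScalarMap:
    arr = np.full(grid.shape, np.nan)
    arr[...] = values
    return ScalarMap(grid, arr, unit)


def random_mask(grid: Grid, rng: np.random.Generator, p: float = 0.3) -> BinaryMask:
    return BinaryMask(grid, rng.random(grid.shape) < p)
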