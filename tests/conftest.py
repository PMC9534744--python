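import numpy as np
import pandas as pd
import pytest

from chronorisk.grids import GridSpec, PeriodSpec
from chronorisk.io import CovariateStack
from chronorisk.simulate import SimulationParams, simulate_all


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A 12 x 10 cell world, cheap enough for per-test simulation."""
    return SimulationParams(n_cells_x=12, n_cells_y=10, n_extant=40, seed=7)


@pytest.fixture(scope="session")
def small_world(small_params):
    """(stack, records, truth, extant, polygon) for the small world."""
    return simulate_all(small_params)


@pytest.fixture()
def grid10() -> GridSpec:
    return GridSpec(100.0, 20.0, 0.5, 10, 10)


@pytest.fixture()
def periods10() -> PeriodSpec:
    return PeriodSpec(1700, 30, 10)


def make_stack(grid: GridSpec, years, layer_fns) -> CovariateStack:
    """Stack from {name: fn(slice_index, iy, ix) -> value} callables."""
    years = np.asarray(years)
    iy, ix = np.meshgrid(np.arange(grid.n_y), np.arange(grid.n_x), indexing="ij")
    layers = {
        name: np.stack([np.asarray(fn(k, iy, ix), dtype=float) for k in range(len(years))])
        for name, fn in layer_fns.items()
    }
    return CovariateStack(grid, years, layers)


@pytest.fixture()
def uniform_records():
    rng = np.random.default_rng(42)
    n = 60
    return pd.DataFrame({
        "id": np.arange(n),
        "lon": 100.0 + rng.random(n) * 5.0,
        "lat": 20.0 + rng.random(n) * 5.0,
        "year": rng.integers(1700, 2000, n),
        "source": "historical",
    })
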