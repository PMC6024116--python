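import numpy as np
import pytest

from sdmshift.grid import EnvLayer, EnvStack, Grid


@pytest.fixture
def small_grid() -> Grid:
    """4x4 one-degree grid: west 0, south 0, north 4."""
    return Grid(n_rows=4, n_cols=4, west=0.0, south=0.0, resolution=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def make_layer(grid: Grid, values, name: str = "x", kind: str = "continuous",
               mask=None) -> EnvLayer:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(grid.shape, dtype=bool)
    return EnvLayer(name=name, grid=grid, values=values, mask=np.asarray(mask, bool),
                    kind=kind)


def make_stack(grid: Grid, named_values: dict, period: str = "present",
               kinds: dict | None = None) -> EnvStack:
    stack = EnvStack(grid, period)
    kinds = kinds or {}
    for name, vals in named_values.items():
        stack.add(make_layer(grid, vals, name=name, kind=kinds.get(name, "continuous")))
    return stack
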