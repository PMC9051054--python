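import numpy as np
import pandas as pd
import pytest

from paleoniche.grids import Layer, Mask, RasterGrid
from paleoniche.synthetic import EthnoSimSpec, WorldSpec, build_world, gen_ethno_table


@pytest.fixture
def grid():
    """5-km equal-area grid, 20x20 cells."""
    return RasterGrid(20, 20, 5000.0, (3_200_000.0, 3_000_000.0))


@pytest.fixture
def small_world_spec():
    return WorldSpec(seed=42, n_rows=60, n_cols=60)


@pytest.fixture(scope="session")
def world():
    """Shared small synthetic world (60x60, seed 42)."""
    return build_world(WorldSpec(seed=42, n_rows=60, n_cols=60))


@pytest.fixture(scope="session")
def ethno_table():
    """Default (noisy) synthetic forager table, seed 7."""
    return gen_ethno_table(EthnoSimSpec(), seed=7)


@pytest.fixture(scope="session")
def noiseless_ethno():
    """Forager table with zero residual scatter: points exactly on the
    planted log-log laws."""
    spec = EthnoSimSpec(residual_sd={"hunters": 0.0, "gatherers": 0.0,
                                     "fishers": 0.0},
                        trade_fraction=0.0, alt_density_fraction=0.0)
    return gen_ethno_table(spec, seed=3)
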