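import numpy as np
import pytest

from demescape import (Landscape, SimParams, make_deme_grid, simulate_forward)


@pytest.fixture
def flat_grid():
    """5x5 fully suitable grid."""
    land = Landscape(n_rows=5, n_cols=5, elevation=np.full((5, 5), 1600.0))
    return make_deme_grid(land, 1400.0)


@pytest.fixture
def single_deme_grid():
    land = Landscape(n_rows=1, n_cols=1, elevation=np.array([[1600.0]]))
    return make_deme_grid(land, 1400.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def constant_trace(grid, n=100, t_onset=2000, seed=0):
    """A single-deme trace with constant population size ``n``."""
    params = SimParams(model="GDD", t_onset=t_onset, n_ancestral=n,
                       growth_rate=0.0, migration_rate=0.0,
                       carrying_capacity=n, seed=seed)
    return simulate_forward(grid, params, origin_deme=0)
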