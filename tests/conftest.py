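import numpy as np
import pytest

from patchwalk import CellMapSpec, generate_cell_map
from patchwalk.scheduler import CellSite


@pytest.fixture
def cell_map():
    """Deterministic 9-cell map over the default 200x200 um field."""
    return generate_cell_map(CellMapSpec(), seed=7)


@pytest.fixture
def line_cells():
    """Cells spaced 50 um apart along x at fixed depth — easy to reason about."""
    return [CellSite(id=i + 1, position=(50.0 * i, 0.0, 50.0)) for i in range(6)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
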