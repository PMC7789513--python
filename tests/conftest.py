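import numpy as np
import pytest

from bymtrend import MortalityPanel, adjacency_from_edges
from bymtrend.simulate import ScenarioConfig, make_lattice, simulate_panel


@pytest.fixture
def path3():
    """3-node path graph a-b-c."""
    return adjacency_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def lattice33():
    return make_lattice(3, 3, "rook")


@pytest.fixture
def tiny_panel():
    return MortalityPanel(
        area_ids=("a", "b"),
        years=(2011, 2012),
        births=np.array([[1000, 1100], [500, 450]]),
        deaths=np.array([[20, 18], [9, 12]]),
    )


@pytest.fixture
def small_dataset():
    """3x3 lattice, 5 years, moderate spatial structure; known truth."""
    return simulate_panel(
        ScenarioConfig(n_rows=3, n_cols=3, n_years=5, seed=42,
                       births_range=(5_000, 20_000))
    )


def write_panel_csv(panel: MortalityPanel, path):
    panel.to_frame().to_csv(path, index=False)
    return path
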