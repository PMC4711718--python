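import numpy as np
import pytest

from lungphantom import GrowthParams, Tree, VoxelGrid, make_fixture_case


@pytest.fixture
def uniform_map():
    """Uniform demand on a 51^3 unit-spacing grid."""
    return VoxelGrid(np.ones((51, 51, 51)))


@pytest.fixture
def single_segment_tree():
    """Root at origin-side, one terminal 10 mm away along x."""
    t = Tree.with_root((5.0, 25.0, 25.0))
    t.add_child(t.root_id, (15.0, 25.0, 25.0))
    return t


@pytest.fixture
def default_params():
    return GrowthParams(n_terminals=1, p0=(5.0, 25.0, 25.0), seed=0)


@pytest.fixture(scope="session")
def fixture_case():
    """One deterministic synthetic labeled case shared across tests."""
    return make_fixture_case(seed=1)
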