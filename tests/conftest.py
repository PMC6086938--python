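import numpy as np
import pytest

from codextk import phantoms


@pytest.fixture(scope="session")
def dense_truth():
    """Standard densely packed 200-cell phantom (fixed fixture seed)."""
    return phantoms.make_cell_map(phantoms.standard_dense_spec())


@pytest.fixture(scope="session")
def dense_stack(dense_truth):
    return phantoms.render_image_stack(dense_truth)


@pytest.fixture(scope="session")
def easy_truth():
    """Well-separated 40-cell phantom (centers >= 3 radii apart)."""
    return phantoms.make_cell_map(phantoms.easy_spec())


@pytest.fixture(scope="session")
def easy_stack(easy_truth):
    return phantoms.render_image_stack(easy_truth)


@pytest.fixture(scope="session")
def adjacency_truth():
    """Dense two-type phantom with mutually exclusive markers."""
    return phantoms.make_cell_map(phantoms.adjacency_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
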