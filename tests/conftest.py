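import numpy as np
import pytest

import elastree as et


@pytest.fixture(scope="session")
def y_tree():
    """Y-shaped fixture: root branch splitting into two arms, with truth."""
    return et.y_tree_fixture(seed=42)


@pytest.fixture(scope="session")
def y_tree_result(y_tree):
    """Full default pipeline run on the Y-tree fixture."""
    m, truth = y_tree
    res = et.run_pipeline(m, config=et.RunConfig(random_seed=42))
    return m, truth, res


@pytest.fixture(scope="session")
def y_points(y_tree_result):
    """Embedded cell coordinates of the Y-tree fixture."""
    _, _, res = y_tree_result
    return res.embedding.coords


@pytest.fixture(scope="session")
def line_data():
    """Noiseless 1D curve embedded in 50 dimensions (arc-length known)."""
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0, 1, 200))
    basis = rng.normal(size=(2, 50))
    X = np.column_stack([np.cos(t), np.sin(t)]) @ basis
    return X, t
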