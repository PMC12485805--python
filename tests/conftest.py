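import numpy as np
import pytest
import scipy.sparse as sp

from picsim import CountDataset
from picsim.fixtures import FixtureSpec, generate_counts_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A 500-peak x 200-cell forward simulation with truth attached."""
    return generate_counts_fixture(FixtureSpec(n_peaks=500, n_cells=200, seed=11))


@pytest.fixture
def toy_counts():
    """Tiny deterministic matrix for hand-checkable assertions."""
    mat = np.array(
        [
            [0, 2, 1, 0],
            [4, 0, 0, 1],
            [0, 0, 0, 0],
            [1, 1, 2, 3],
        ]
    )
    return CountDataset(sp.csr_matrix(mat))


def make_counts(mat) -> CountDataset:
    return CountDataset(sp.csr_matrix(np.asarray(mat)))
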