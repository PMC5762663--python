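import numpy as np
import pandas as pd
import pytest

from oceandecay.pairwise import PairwiseMatrix
from oceandecay.testbed import default_test_bed


def random_distance_matrix(n: int, rng: np.random.Generator) -> PairwiseMatrix:
    """Random symmetric distance matrix with zero diagonal."""
    M = rng.random((n, n))
    D = (M + M.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return PairwiseMatrix(D, [f"s{i}" for i in range(n)], kind="distance")


@pytest.fixture(scope="session")
def test_bed():
    """The packaged double-gyre test bed (25 stations + transit matrix)."""
    return default_test_bed(n_stations=25, seed=0)


@pytest.fixture
def small_community():
    """Hand-built 4-station presence-absence table with known overlaps."""
    data = {
        # station A and B share 5 taxa; A has 3 private, B has 2 private
        "A": [1, 1, 1, 1, 1, 1, 1, 1, 0, 0],
        "B": [1, 1, 1, 1, 1, 0, 0, 0, 1, 1],
        "C": [1, 1, 1, 1, 1, 1, 1, 1, 0, 0],  # identical to A
        "D": [0, 0, 0, 0, 0, 0, 0, 0, 0, 1],  # disjoint from A
    }
    return pd.DataFrame(data).T
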