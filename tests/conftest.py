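import numpy as np
import pytest

from mscluster import make_distance_matrix


@pytest.fixture
def toy_t1():
    """Five elements in two well-separated families.

    d(A,B)=1, d(A,C)=d(B,C)=2, d(D,E)=1, every cross-family pair = 10.
    """
    labels = list("ABCDE")
    values = np.full((5, 5), 10.0)
    np.fill_diagonal(values, 0.0)
    values[0, 1] = values[1, 0] = 1.0
    values[0, 2] = values[2, 0] = 2.0
    values[1, 2] = values[2, 1] = 2.0
    values[3, 4] = values[4, 3] = 1.0
    return make_distance_matrix(values, labels)


def random_dm(rng, n, low=0.0, high=1.0):
    """Random symmetric hollow matrix with i.i.d. uniform off-diagonals."""
    values = rng.uniform(low, high, size=(n, n))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return make_distance_matrix(values, [f"n{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
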