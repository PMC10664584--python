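import numpy as np
import pytest

from cellpam import ExpressionMatrix, compute_dissimilarity


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sparse_counts(rng):
    """Random sparse 20×10 count matrix as an ExpressionMatrix."""
    X = rng.poisson(0.8, size=(20, 10))
    return ExpressionMatrix(
        X, [f"c{i}" for i in range(20)], [f"g{j}" for j in range(10)]
    )


@pytest.fixture
def line_dissim():
    """L1 dissimilarities of points at {0, 1, 10, 11}: two tight pairs."""
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    return compute_dissimilarity(X, metric="L1")


def naive_td(square, medoids):
    """TD of a medoid set by direct recomputation from the square matrix."""
    return square[list(medoids)].min(axis=0).sum()
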