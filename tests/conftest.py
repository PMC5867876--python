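import numpy as np
import pytest

from xenodiff import ExpressionMatrix


def make_matrix(values, labels, mask=None, cell_ids=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values,
        cell_ids or [f"c{i + 1}" for i in range(n)],
        gene_ids or [f"g{j + 1}" for j in range(p)],
        np.asarray(labels),
        np.zeros_like(values, dtype=bool) if mask is None else np.asarray(mask, bool),
    )


@pytest.fixture
def tiny_matrix():
    """4 cells x 3 genes, two classes, no missing data."""
    return make_matrix(
        [[1.0, 2.0, 0.5], [1.1, 2.1, 0.4], [5.0, 6.0, 0.6], [5.1, 6.1, 0.5]],
        ["human", "human", "pdx", "pdx"],
    )


@pytest.fixture
def separable_matrix():
    """Two classes cleanly separated on the first gene (60 cells)."""
    rng = np.random.default_rng(0)
    n = 60
    labels = np.array(["human"] * 20 + ["pdx"] * 40)
    X = rng.normal(2.0, 1.0, size=(n, 4))
    X[:20, 0] += 8.0
    return make_matrix(X, labels)
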