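import numpy as np
import pytest

from sctiger.matrix import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 cells with simple integer counts."""
    return ExpressionMatrix(
        counts=np.array([
            [1.0, 0.0, 2.0, 3.0],
            [0.0, 5.0, 1.0, 0.0],
            [2.0, 2.0, 2.0, 2.0],
        ]),
        gene_ids=["GA", "GB", "GC"],
        cell_ids=["c1", "c2", "c3", "c4"],
    )


@pytest.fixture
def blob_matrix():
    """Two well-separated Gaussian blobs of 50 cells each (20 genes)."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 0.3, size=(20, 50))
    b = rng.normal(4.0, 0.3, size=(20, 50))
    counts = np.abs(np.concatenate([a, b], axis=1))
    labels = np.array([0] * 50 + [1] * 50)
    m = ExpressionMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(20)],
        cell_ids=[f"c{i}" for i in range(100)],
    )
    return m, labels


@pytest.fixture
def gradient_matrix():
    """Cells along a 1-D expression gradient (smooth trajectory), shuffled."""
    rng = np.random.default_rng(7)
    n_cells, n_genes = 80, 15
    pos = np.linspace(0, 1, n_cells)
    centers = rng.uniform(0, 1, n_genes)
    widths = rng.uniform(0.15, 0.4, n_genes)
    prof = np.exp(-((pos[None, :] - centers[:, None]) / widths[:, None]) ** 2)
    counts = np.clip(prof + rng.normal(0, 0.03, size=prof.shape), 0, None)
    perm = rng.permutation(n_cells)
    m = ExpressionMatrix(
        counts=counts[:, perm],
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
    )
    return m, pos[perm]
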