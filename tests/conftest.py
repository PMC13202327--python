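import numpy as np
import pytest

from scuddo.contacts_io import CellEnsemble, ContactMap


def make_map(cell, chrom, matrix):
    return ContactMap(cell, chrom, np.asarray(matrix, dtype=np.int64))


def make_ensemble(per_cell_chrom, labels=None):
    """Build a CellEnsemble from {(cell, chrom): matrix}."""
    cells = sorted({c for c, _ in per_cell_chrom})
    chroms = sorted({k for _, k in per_cell_chrom})
    maps = {(c, k): make_map(c, k, m) for (c, k), m in per_cell_chrom.items()}
    return CellEnsemble(cells, chroms, maps, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_symmetric_counts(rng):
    """Factory for random symmetric nonnegative integer matrices."""
    def _make(n, high=5):
        A = rng.integers(0, high, size=(n, n))
        return np.triu(A) + np.triu(A, k=1).T
    return _make


@pytest.fixture
def small_ensemble(random_symmetric_counts):
    """3 cells x 2 chromosomes with dense-ish random counts."""
    data = {}
    for c in ("c0", "c1", "c2"):
        data[(c, "chr1")] = random_symmetric_counts(8, 6)
        data[(c, "chr2")] = random_symmetric_counts(6, 6)
    return make_ensemble(data)
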