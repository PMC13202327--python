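"""k-means++ labeling of embeddings and exact partition-agreement metrics.

The adjusted Rand index (ARI) and normalized mutual information (NMI) are
computed from the l x l contingency table between ground-truth and predicted
partitions.  ARI is pair-counting agreement corrected for chance (1 =
identical partitions, 0 = chance level, negative = worse than chance); NMI
is the mutual information of the two label distributions normalized by the
geometric mean of their entropies (log base 2), in [0, 1].  ARI is the more
informative score when clusters are similar in size, NMI when they are
unbalanced; the pipeline reports both.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass
from math import comb, log2

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "ClusterResult",
    "ScoreSummary",
    "contingency_table",
    "kmeans_pp",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "score_embedding",
    "derive_seed",
]


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage/per-repeat seed below 2**31."""
    ss = np.random.SeedSequence(
        [master_seed & 0x7FFFFFFF, zlib.crc32(stage.encode()) % (2 ** 31),
         index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _as_codes(labels) -> np.ndarray:
    """Map arbitrary hashable labels to dense integer codes 0..l-1."""
    labels = list(labels)
    uniq = {}
    codes = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        codes[i] = uniq.setdefault(lab, len(uniq))
    return codes


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts beta[i, j] = |X_i intersect Y_j| with marginals."""

    beta: np.ndarray
    row_sums: np.ndarray  # Gamma
    col_sums: np.ndarray  # Delta
    total: int


def contingency_table(truth, pred) -> ContingencyTable:
    t = _as_codes(truth)
    p = _as_codes(pred)
    if t.shape != p.shape:
        raise ValueError("labelings must cover the same cells")
    if t.size < 2:
        raise ValueError("need at least 2 cells")
    beta = np.zeros((t.max() + 1, p.max() + 1), dtype=np.int64)
    np.add.at(beta, (t, p), 1)
    return ContingencyTable(beta, beta.sum(axis=1), beta.sum(axis=0),
                            int(t.size))


def adjusted_rand_index(truth, pred) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Uses exact integer binomial arithmetic, so the index is exact for any
    partition size.  The degenerate case where both the index and its
    expectation equal the maximum (e.g. all-singletons vs one-cluster on
    both sides yielding a 0/0) returns 0 with a warning.
    """
    ct = contingency_table(truth, pred)
    sum_cells = sum(comb(int(b), 2) for b in ct.beta.ravel())
    sum_rows = sum(comb(int(g), 2) for g in ct.row_sums)
    sum_cols = sum(comb(int(d), 2) for d in ct.col_sums)
    n_pairs = comb(ct.total, 2)
    expected = sum_rows * sum_cols / n_pairs
    max_index = 0.5 * (sum_rows + sum_cols)
    denom = max_index - expected
    if denom == 0:
        warnings.warn("degenerate partitions (ARI denominator zero); "
                      "returning 0")
        return 0.0
    return float((sum_cells - expected) / denom)


def normalized_mutual_information(truth, pred) -> float:
    """Mutual information normalized by the geometric mean of entropies.

    All frequencies come from the contingency table; 0 * log 0 := 0, and a
    zero-entropy (single-cluster) partition on either side makes the
    normalization degenerate, returning 0 with a warning.
    """
    ct = contingency_table(truth, pred)
    a = ct.total
    h_row = -sum((g / a) * log2(g / a) for g in ct.row_sums if g > 0)
    h_col = -sum((d / a) * log2(d / a) for d in ct.col_sums if d > 0)
    if h_row == 0 or h_col == 0:
        warnings.warn("single-cluster partition (zero entropy); NMI "
                      "undefined, returning 0")
        return 0.0
    mi = 0.0
    for i in range(ct.beta.shape[0]):
        for j in range(ct.beta.shape[1]):
            b = ct.beta[i, j]
            if b == 0:
                continue
            h_ij = b / a
            mi += h_ij * log2(h_ij / ((ct.row_sums[i] / a)
                                      * (ct.col_sums[j] / a)))
    return float(mi / np.sqrt(h_row * h_col))


@dataclass(frozen=True)
class ClusterResult:
    """Predicted labels of one k-means++ run."""

    labels: np.ndarray  # integer labels 0..l-1, one per cell
    inertia: float
    n_init: int
    seed: int


def kmeans_pp(C: np.ndarray, l: int, n_init: int = 10,
              seed: int = 0) -> ClusterResult:
    """k-means with k-means++ seeding; best of ``n_init`` restarts.

    Deterministic for a fixed seed.  A final solution with an empty cluster
    (fewer than ``l`` distinct labels) is an error state.
    """
    C = np.atleast_2d(np.asarray(C, dtype=np.float64))
    if C.shape[0] < l:
        raise ValueError("fewer points than clusters")
    km = KMeans(n_clusters=l, init="k-means++", n_init=n_init,
                max_iter=300, tol=1e-4, random_state=seed)
    labels = km.fit_predict(C)
    if len(np.unique(labels)) < l:
        raise RuntimeError("k-means produced an empty cluster")
    return ClusterResult(labels, float(km.inertia_), n_init, seed)


@dataclass(frozen=True)
class ScoreSummary:
    mean_ari: float
    sd_ari: float
    mean_nmi: float
    sd_nmi: float
    repeats: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean_ari": self.mean_ari, "sd_ari": self.sd_ari,
            "mean_nmi": self.mean_nmi, "sd_nmi": self.sd_nmi,
            "repeats": self.repeats, "seed": self.seed,
        }


def score_embedding(C: np.ndarray, truth, l: int, repeats: int = 10,
                    seed: int = 0, n_init: int = 10) -> ScoreSummary:
    """Cluster an embedding ``repeats`` times and summarize ARI/NMI.

    Each repeat uses a distinct seed derived deterministically from the
    master seed, mirroring the protocol of clustering several independent
    embeddings and averaging the scores.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    truth = list(truth)
    aris, nmis = [], []
    for rep in range(repeats):
        res = kmeans_pp(C, l, n_init=n_init,
                        seed=derive_seed(seed, "kmeans", rep))
        aris.append(adjusted_rand_index(truth, res.labels))
        nmis.append(normalized_mutual_information(truth, res.labels))
    aris, nmis = np.array(aris), np.array(nmis)
    return ScoreSummary(float(aris.mean()), float(aris.std(ddof=0)),
                        float(nmis.mean()), float(nmis.std(ddof=0)),
                        repeats, seed)
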