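"""Superdiagonal band features and per-offset cell-cell distance matrices.

Entries on the ``w``-th superdiagonal of a contact matrix are contacts at a
fixed genomic separation of ``w`` bins, so each offset isolates one spatial
scale of chromatin folding.  For every offset the pipeline builds two
complementary views of each cell:

* the z-scored band profile ``e'`` (band normalization removes the strong
  distance-decay trend so cells are compared within one separation scale),
* the ternary signed-difference vector ``f = sgn(grad e')``, which keeps
  only the up/down shape of the profile and is insensitive to amplitude.

Cosine distances over both views are combined multiplicatively via
element-wise exponentiation into a single matrix ``K^w`` per offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imputation import ImputedMap

logger = logging.getLogger(__name__)

__all__ = [
    "DiagonalFeature",
    "DiagonalDistanceSet",
    "extract_superdiagonal",
    "build_embedding_vector",
    "cosine_distance_matrix",
    "combine_distances",
    "features_for_all_offsets",
]


@dataclass(frozen=True)
class DiagonalFeature:
    """One cell's band features at one superdiagonal offset."""

    offset_w: int
    cell_id: str
    e_vec: np.ndarray  # z-scored concatenated band profile, length b(r-w)
    f_vec: np.ndarray  # ternary signed differences, entries in {-1, 0, 1}


@dataclass(frozen=True)
class DiagonalDistanceSet:
    """Cell-by-cell distances at one offset: cosine on e', cosine on f,
    and their exponentiated combination K."""

    offset_w: int
    D_e: np.ndarray
    D_f: np.ndarray
    K: np.ndarray


def extract_superdiagonal(B: np.ndarray, w: int) -> np.ndarray:
    """Entries (B[0, w], B[1, 1+w], ..., B[r-1-w, r-1]) of length r - w."""
    B = np.asarray(B)
    r = B.shape[0]
    if not 0 <= w <= r - 1:
        raise ValueError(f"offset w={w} out of range for r={r}")
    return np.diagonal(B, offset=w).copy()


def build_embedding_vector(maps: list[ImputedMap] | list[np.ndarray], w: int,
                           cell_id: str = "",
                           literal_last_entry: bool = False) -> DiagonalFeature:
    """Concatenate one cell's superdiagonals across chromosomes, z-score,
    and trinarize.

    ``e`` is the concatenation (in chromosome order) of the ``w``-th
    superdiagonals; ``e'`` is its z-score with the sample standard deviation
    (denominator ``n - 1``); ``f`` holds ``sgn(e'_a - e'_{a+1})`` for
    consecutive entries, and the final entry is ``sgn(e'_last)`` so the
    vector is genuinely ternary (``literal_last_entry=True`` stores the raw
    ``e'_last`` instead).

    A constant band has no scale: its z-score is defined as the zero vector,
    which contributes no discriminative signal downstream.
    """
    arrays = [m.matrix if isinstance(m, ImputedMap) else np.asarray(m)
              for m in maps]
    r = arrays[0].shape[0]
    if any(a.shape[0] != r for a in arrays):
        raise ValueError("all imputed maps must share the dimension r")
    if w > r - 2:
        raise ValueError(f"offset w={w} leaves segments shorter than 2 "
                         f"(r={r})")
    e = np.concatenate([extract_superdiagonal(a, w) for a in arrays])
    mu = e.mean()
    sd = e.std(ddof=1)
    if sd == 0:
        logger.warning("constant band (cell=%s, w=%d); z-score set to zero",
                       cell_id, w)
        e_prime = np.zeros_like(e)
    else:
        e_prime = (e - mu) / sd
    f = np.empty_like(e_prime)
    f[:-1] = np.sign(e_prime[:-1] - e_prime[1:])
    f[-1] = e_prime[-1] if literal_last_entry else np.sign(e_prime[-1])
    return DiagonalFeature(w, cell_id, e_prime, f)


def cosine_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances 1 - cos(v_i, v_j) for rows of ``vectors``.

    Zero-magnitude rows get distance 1 to every nonzero row (maximal
    ignorance: no direction information) and 0 to other zero rows, keeping
    the matrix finite, symmetric and zero-diagonal.
    """
    V = np.asarray(vectors, dtype=np.float64)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("need at least two vectors of equal length")
    norms = np.linalg.norm(V, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    U = V / safe[:, None]
    D = 1.0 - U @ U.T
    D[zero, :] = 1.0
    D[:, zero] = 1.0
    D[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return np.clip(D, 0.0, 2.0)


def combine_distances(D_e: np.ndarray, D_f: np.ndarray) -> np.ndarray:
    """Element-wise exponentiated combination K = exp(D_e + D_f).

    Monotone in each argument; the diagonal is exp(0) = 1 and entries lie in
    [1, e^4] since each cosine distance is in [0, 2].
    """
    D_e = np.asarray(D_e, dtype=np.float64)
    D_f = np.asarray(D_f, dtype=np.float64)
    if D_e.shape != D_f.shape:
        raise ValueError("distance matrices must share a shape")
    return np.exp(D_e + D_f)


def features_for_all_offsets(imputed: dict[tuple[str, str], ImputedMap],
                             cells: list[str], chroms: list[str],
                             zeta: int,
                             literal_last_entry: bool = False
                             ) -> list[DiagonalDistanceSet]:
    """Build one :class:`DiagonalDistanceSet` per offset w = 0..zeta.

    Offsets are mutually independent (parallelizable); the returned list is
    ordered by offset.
    """
    r = next(iter(imputed.values())).r
    if zeta > r - 2:
        raise ValueError(
            f"zeta={zeta} too large for r={r}; maximum admissible zeta is "
            f"{r - 2}")
    out = []
    for w in range(zeta + 1):
        E = np.empty((len(cells), len(chroms) * (r - w)))
        F = np.empty_like(E)
        for si, cell in enumerate(cells):
            feat = build_embedding_vector(
                [imputed[(cell, k)] for k in chroms], w, cell,
                literal_last_entry)
            E[si] = feat.e_vec
            F[si] = feat.f_vec
        D_e = cosine_distance_matrix(E)
        D_f = cosine_distance_matrix(F)
        out.append(DiagonalDistanceSet(w, D_e, D_f,
                                       combine_distances(D_e, D_f)))
    return out
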