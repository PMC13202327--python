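"""Dimensionality-reduction cascade from per-offset distance matrices to the
latent embedding V and the spectral embedding C.

The cascade is: per-offset nonmetric MDS (to p dims) + PCA (to q dims) ->
column-concatenation into R -> feature-wise softmax -> L1 distances S ->
MDS to the latent dimension epsilon (V) -> Shi-Malik normalized spectral
embedding (C, with l - 1 columns for l expected cell types).

Nonmetric MDS only preserves the *rank order* of the input dissimilarities,
which is the right invariance here: the per-offset matrices K^w are
exponentiated combinations of cosine distances whose absolute scale is not
meaningful.  A classical (Torgerson) MDS mode is provided as the fast-mode
shortcut; on genuinely Euclidean dissimilarities it is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import smacof

logger = logging.getLogger(__name__)

__all__ = [
    "ReductionParams",
    "EmbeddingBundle",
    "classical_mds",
    "reduce_offset",
    "stack_and_normalize",
    "l1_distance",
    "embed_latent",
    "spectral_embed",
    "build_embeddings",
]


@dataclass(frozen=True)
class ReductionParams:
    """Cascade dimensions and reproducibility settings.

    p is the intermediate MDS dimension per offset, q the per-offset PCA
    dimension, zeta the largest superdiagonal offset, epsilon the latent
    dimension of V, and n_labels_l the number of expected cell types
    (C gets l - 1 columns).
    """

    p: int = 30
    q: int = 5
    zeta: int = 25
    epsilon: int = 5
    n_labels_l: int = 2
    mds_mode: str = "nonmetric"  # or "classical"
    seed: int = 0
    mds_max_iter: int = 300
    mds_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.q > self.p:
            raise ValueError("q must not exceed p")
        if self.epsilon < 1:
            raise ValueError("epsilon must be >= 1")
        if self.n_labels_l < 2:
            raise ValueError("need at least 2 labels")
        if self.mds_mode not in ("nonmetric", "classical"):
            raise ValueError(f"unknown mds_mode {self.mds_mode!r}")


@dataclass
class EmbeddingBundle:
    """All intermediate and final embeddings of one run."""

    U_blocks: list[np.ndarray]
    R: np.ndarray
    R_soft: np.ndarray
    S: np.ndarray
    V: np.ndarray
    C: np.ndarray


def classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson classical scaling of a dissimilarity matrix.

    Double-centers the squared dissimilarities, takes the top ``dim``
    eigenpairs and scales eigenvectors by sqrt(eigenvalue); negative
    eigenvalues (non-Euclidean input) contribute zero coordinates.  Exact on
    Euclidean distance matrices up to rotation/reflection.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D ** 2) @ J
    Bmat = 0.5 * (Bmat + Bmat.T)
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[order], 0.0, None)
    X = evecs[:, order] * np.sqrt(lam)
    # deterministic sign: largest-magnitude coordinate of each axis positive
    for j in range(X.shape[1]):
        k = np.argmax(np.abs(X[:, j]))
        if X[k, j] < 0:
            X[:, j] = -X[:, j]
    return X


def _mds_embed(D: np.ndarray, dim: int, params: ReductionParams) -> np.ndarray:
    """Embed a dissimilarity matrix into ``dim`` dimensions.

    Nonmetric mode runs SMACOF majorization of Kruskal stress-1 initialized
    from the classical solution (a deterministic, well-spread start); fast /
    classical mode returns the Torgerson solution directly.
    """
    n = D.shape[0]
    if dim >= n:
        logger.warning("MDS dimension %d >= n=%d; lowering to %d",
                       dim, n, n - 1)
        dim = n - 1
    init = classical_mds(D, dim)
    if params.mds_mode == "classical":
        return init
    X, stress = smacof(
        D, metric=False, n_components=dim, init=init, n_init=1,
        max_iter=params.mds_max_iter, eps=params.mds_eps,
        random_state=params.seed, normalized_stress=True)
    logger.debug("SMACOF final normalized stress %.3e", stress)
    return X


def reduce_offset(K: np.ndarray, params: ReductionParams) -> np.ndarray:
    """Nonmetric MDS (p dims) + centered PCA (q dims) of one offset's
    distance matrix.

    The diagonal of K is 1 by construction (exp of zero distance); MDS
    requires zero self-dissimilarity, so the diagonal is zeroed first --
    legitimate for nonmetric MDS, which only uses the off-diagonal ranks.
    """
    K = np.asarray(K, dtype=np.float64).copy()
    np.fill_diagonal(K, 0.0)
    a = K.shape[0]
    p = params.p
    if a <= p:
        logger.warning("a=%d <= p=%d; lowering p to %d", a, p, a - 1)
        p = a - 1
    X = _mds_embed(K, p, params)
    q = min(params.q, X.shape[1])
    pca = PCA(n_components=q, svd_solver="full")
    return pca.fit_transform(X)


def stack_and_normalize(U_blocks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-offset blocks into R and softmax-normalize feature-wise.

    The softmax runs over cells within each feature column (with max
    subtraction for overflow safety), so every column of R_soft sums to 1.
    """
    a = U_blocks[0].shape[0]
    if any(b.shape[0] != a for b in U_blocks):
        raise ValueError("all blocks must share the number of cells")
    R = np.concatenate(U_blocks, axis=1)
    shifted = R - R.max(axis=0, keepdims=True)
    E = np.exp(shifted)
    R_soft = E / E.sum(axis=0, keepdims=True)
    return R, R_soft


def l1_distance(R_soft: np.ndarray) -> np.ndarray:
    """Pairwise L1 (cityblock) distances between the rows of R_soft."""
    return cdist(R_soft, R_soft, metric="cityblock")


def embed_latent(S: np.ndarray, params: ReductionParams) -> np.ndarray:
    """MDS of the L1 distance matrix S into the latent dimension epsilon."""
    return _mds_embed(np.asarray(S, dtype=np.float64), params.epsilon, params)


def spectral_embed(V: np.ndarray, l: int) -> np.ndarray:
    """Shi-Malik normalized spectral embedding of the latent space V.

    A Gaussian similarity ``exp(-Z^2)`` on pairwise latent distances is
    sparsified to each point's ceil(ln a) nearest neighbors (self excluded,
    symmetrized by union so sparse graphs stay connected), and the
    generalized eigenproblem ``L u = lambda D u`` of the random-walk
    Laplacian is solved via the symmetric normalization ``D^{-1/2} L
    D^{-1/2}`` (stable for near-zero eigenvalues).  The returned columns are
    the eigenvectors of the l - 1 smallest eigenvalues after the trivial
    (constant) one, in ascending order, each scaled so its
    largest-magnitude entry is positive.

    If the neighbor graph is disconnected the zero eigenvalue has higher
    multiplicity; those eigenvectors encode the components and are kept.
    """
    V = np.asarray(V, dtype=np.float64)
    a = V.shape[0]
    if not 2 <= l <= a:
        raise ValueError(f"need 2 <= l <= a, got l={l}, a={a}")
    Z = squareform(pdist(V))
    A = np.exp(-Z ** 2)
    k = int(np.ceil(np.log(a)))
    k = min(max(k, 1), a - 1)
    W = np.zeros_like(A)
    np.fill_diagonal(A, 0.0)  # self excluded from neighbor lists
    for i in range(a):
        nn = np.argsort(A[i])[::-1][:k]
        W[i, nn] = A[i, nn]
    W = np.maximum(W, W.T)  # union symmetrization
    deg = W.sum(axis=1)
    if (deg == 0).any():
        raise ValueError("isolated vertex in the nearest-neighbor graph")
    d_isqrt = 1.0 / np.sqrt(deg)
    L_sym = np.eye(a) - (d_isqrt[:, None] * W) * d_isqrt[None, :]
    L_sym = 0.5 * (L_sym + L_sym.T)
    evals, evecs = np.linalg.eigh(L_sym)
    n_zero = int(np.sum(evals < 1e-8))
    if n_zero > 1:
        logger.warning("neighbor graph has %d connected components", n_zero)
    U = evecs * d_isqrt[:, None]  # back-transform to random-walk eigenvectors
    C = U[:, 1:l]
    C = C.copy()
    for j in range(C.shape[1]):
        m = np.argmax(np.abs(C[:, j]))
        if C[m, j] < 0:
            C[:, j] = -C[:, j]
    return C


def build_embeddings(distance_sets, params: ReductionParams) -> EmbeddingBundle:
    """Run the full cascade from per-offset distance sets to V and C."""
    U_blocks = [reduce_offset(ds.K, params) for ds in distance_sets]
    R, R_soft = stack_and_normalize(U_blocks)
    S = l1_distance(R_soft)
    V = embed_latent(S, params)
    C = spectral_embed(V, params.n_labels_l)
    return EmbeddingBundle(U_blocks, R, R_soft, S, V, C)
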