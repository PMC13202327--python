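"""Synthetic single-cell Hi-C ensembles with planted cell-type structure.

The generator emulates the statistical features of real single-cell
intrachromosomal maps that the pipeline exploits:

* a power-law distance decay of contact probability, ``P(i, j)
  proportional to (1 + |i - j|)^-gamma`` -- the dominant trend of any Hi-C
  map;
* TAD-like blocks of elevated self-contact along the diagonal, whose
  boundary positions differ between cell types (shifted by a fixed number
  of bins), since varying domain boundaries are what distinguishes cell
  types structurally;
* extreme sparsity: each cell receives a fixed total number of contacts,
  sampled multinomially from its type's probability profile, so maps at a
  few thousand contacts are mostly zeros off the diagonal, as in real
  experiments.

The fixed-total multinomial scheme makes per-cell count conservation exact
and the coverage-filter thresholds precisely controllable in tests.  What
the generator does *not* model: polymer physics, A/B compartments,
cell-cycle (replication/mitotic) structure, or trans contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts_io import CellEnsemble, ContactMap

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "make_type_profiles", "sample_ensemble",
           "recovery_experiment"]


def recovery_experiment(spec: "SyntheticSpec", config=None):
    """Sample an ensemble, run the full pipeline, score the planted labels.

    Thin convenience front-end to :func:`scuddo.pipeline.recovery_experiment`
    (imported lazily to keep this module free of pipeline dependencies).
    """
    from .pipeline import recovery_experiment as _run

    return _run(spec, config)

#: Multiplicative contact enrichment inside a TAD-like block relative to the
#: background decay at the same separation.
BLOCK_ENRICHMENT = 8.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Ensemble design: sizes, sparsity, and strength of the planted signal.

    ``contacts_per_cell`` controls sparsity (real 1 Mb single-cell maps span
    roughly 5k-500k contacts); ``boundary_shift`` is the number of bins by
    which successive cell types' block boundaries are displaced (0 = no
    signal); ``within_type_noise`` mixes each cell's type profile toward the
    type-averaged mean profile (1 = types indistinguishable).
    """

    n_cells_a: int = 120
    n_types_l: int = 3
    type_proportions: tuple[float, ...] | None = None
    n_chroms_b: int = 4
    chrom_sizes: tuple[int, ...] = (60, 55, 50, 45)
    contacts_per_cell: int = 100_000
    decay_exponent: float = 1.0
    block_count: int = 5
    boundary_shift: int = 4
    within_type_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_proportions is None:
            object.__setattr__(
                self, "type_proportions",
                tuple([1.0 / self.n_types_l] * self.n_types_l))
        props = np.asarray(self.type_proportions, dtype=float)
        if len(props) != self.n_types_l:
            raise ValueError("one proportion per type required")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if len(self.chrom_sizes) != self.n_chroms_b:
            raise ValueError("one size per chromosome required")
        if min(self.chrom_sizes) < 2 or self.n_cells_a < 2:
            raise ValueError("all sizes must be positive (>= 2 bins/cells)")
        if not 0.0 <= self.within_type_noise <= 1.0:
            raise ValueError("within_type_noise must be in [0, 1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms_b)]


def _block_labels(n_bins: int, block_count: int, shift: int) -> np.ndarray:
    """Assign each bin to a TAD-like block; boundaries displaced by ``shift``."""
    bounds = np.linspace(0, n_bins, block_count + 1)
    edges = np.round(bounds).astype(int)
    inner = np.clip(edges[1:-1] + shift, 1, n_bins - 1)
    edges = np.concatenate([[0], inner, [n_bins]])
    labels = np.empty(n_bins, dtype=int)
    for bi in range(block_count):
        labels[edges[bi]:edges[bi + 1]] = bi
    return labels


def make_type_profiles(spec: SyntheticSpec) -> list[list[np.ndarray]]:
    """Per-type, per-chromosome contact probability matrices.

    Each profile is the normalized product of a power-law distance-decay
    term and a block-pattern term that multiplies within-block contacts by
    :data:`BLOCK_ENRICHMENT`.  Type ``t`` shifts every internal block
    boundary by ``t * boundary_shift`` bins, so types share the decay trend
    and differ only in domain architecture.  Profiles are symmetric,
    nonnegative, and sum to 1 per chromosome.
    """
    smallest_block = min(spec.chrom_sizes) // spec.block_count
    if spec.boundary_shift and spec.boundary_shift >= smallest_block:
        raise ValueError(
            f"boundary_shift={spec.boundary_shift} >= smallest block width "
            f"{smallest_block}")
    profiles: list[list[np.ndarray]] = []
    for t in range(spec.n_types_l):
        per_chrom = []
        for n in spec.chrom_sizes:
            idx = np.arange(n)
            sep = np.abs(idx[:, None] - idx[None, :])
            decay = (1.0 + sep) ** (-spec.decay_exponent)
            blocks = _block_labels(n, spec.block_count,
                                   t * spec.boundary_shift)
            same = blocks[:, None] == blocks[None, :]
            pattern = np.where(same, BLOCK_ENRICHMENT, 1.0)
            P = decay * pattern
            per_chrom.append(P / P.sum())
        profiles.append(per_chrom)
    return profiles


def sample_ensemble(spec: SyntheticSpec) -> CellEnsemble:
    """Draw a labeled ensemble of sparse symmetric count matrices.

    Each cell draws its type from ``type_proportions``, mixes its type
    profile toward the mean profile with weight ``within_type_noise``, then
    places exactly ``contacts_per_cell`` contacts multinomially: first
    across chromosomes (proportionally to chromosome profile mass, here the
    chromosome's share of unnormalized decay-times-block weight), then
    across the upper triangle of that chromosome's profile.  Every sampled
    pair (i, j) increments both A[i, j] and A[j, i] (once when i = j), so
    the sum over the upper triangle including the diagonal equals
    ``contacts_per_cell`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = make_type_profiles(spec)
    mean_profile = [
        np.mean([profiles[t][k] for t in range(spec.n_types_l)], axis=0)
        for k in range(spec.n_chroms_b)
    ]
    # chromosome weights: share of total bin count (bigger chromosome, more
    # contacts), fixed across types so sparsity per chromosome is comparable
    sizes = np.asarray(spec.chrom_sizes, dtype=float)
    chrom_w = sizes ** 2 / (sizes ** 2).sum()

    cells = [f"cell{s:04d}" for s in range(spec.n_cells_a)]
    types = rng.choice(spec.n_types_l, size=spec.n_cells_a,
                       p=np.asarray(spec.type_proportions))
    labels = {c: f"type{t}" for c, t in zip(cells, types)}
    maps: dict[tuple[str, str], ContactMap] = {}
    chrom_names = spec.chrom_names
    for cell, t in zip(cells, types):
        per_chrom_n = rng.multinomial(spec.contacts_per_cell, chrom_w)
        for k, (name, n_contacts) in enumerate(zip(chrom_names, per_chrom_n)):
            n = spec.chrom_sizes[k]
            P = ((1.0 - spec.within_type_noise) * profiles[t][k]
                 + spec.within_type_noise * mean_profile[k])
            iu, ju = np.triu_indices(n)
            p_up = P[iu, ju].copy()
            # off-diagonal mass appears in both triangles of the symmetric
            # profile; fold it into the upper-triangle sampling weights
            p_up[iu != ju] *= 2.0
            p_up /= p_up.sum()
            counts = rng.multinomial(n_contacts, p_up)
            A = np.zeros((n, n), dtype=np.int64)
            A[iu, ju] = counts
            A = A + np.triu(A, k=1).T
            maps[(cell, name)] = ContactMap(cell, name, A)
    return CellEnsemble(cells, chrom_names, maps, labels)
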