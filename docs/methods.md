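# Methods

This note documents the model implemented by `scuddo`, the parameter
choices that matter, the synthetic data the tests rely on, and the
numerical conventions adopted where the design was genuinely open.

## Input model and filtering

The unit of analysis is an ensemble of *a* cells × *b* chromosomes of
symmetric nonnegative-integer contact matrices $A_s^k$ at a fixed bin size
(1 Mb by default). Trans (interchromosomal) contacts are discarded at read
time. Three quality filters run before any computation:

* **Empty-chromosome filter** (first): a chromosome is dropped for *all*
  cells when its map is all-zero in strictly more than 10% of cells
  (`max_empty_frac = 0.10`; exactly 10% is kept).
* **Per-cell coverage filter**: a cell is removed when its summed
  off-diagonal counts across retained chromosomes are below 5000
  (`min_total_contacts`), or when any single chromosome of $x$ bins has an
  off-diagonal sum below $x$. "Off-diagonal sum" counts both triangles of
  the symmetric matrix; "size $x$" is the bin count (matrix dimension), the
  only reading under which the comparison is dimensionally sensible. The
  5000 threshold sums counts; a `count_entries` flag switches to counting
  distinct nonzero entries, since the phrase admits either reading.
* Sex chromosomes are excluded by default (`include_sex=True` restores
  them); chromosome order is natural sort (chr1 < chr2 < … < chr19 < chrX).

Filtering is idempotent and never mutates its input ensemble.

## Imputation cascade

Each map passes through four stages, producing a dense real $r\times r$
matrix:

1. **Regularized graph Laplacian kernel**
   $\bar A = (2I - D^{-1}(A+I))^{-1}$ with $D$ the degree matrix of $A+I$.
   Since $P = D^{-1}(A+I)$ is row-stochastic, the inverse always exists and
   equals $\tfrac12\sum_{j\ge0}(P/2)^j$: rows of $\bar A$ sum to 1 and all
   entries are nonnegative. The diagonal regularization $+I$ guarantees
   positive degrees even for all-zero maps. Fast mode truncates the series
   at `neumann_order = 8`; the tail is bounded by $(1/2)^{\text{order}}$,
   so 8 terms are accurate to ~4 × 10⁻³ — comfortably inside the accuracy
   loss budgeted for fast mode.
2. **Symmetrize + bicubic resize** to $r = \mathrm{round}(\sum_k n_k / b)$
   (the mean chromosome size; the exact ratio is generally non-integer).
   Resampling uses separable cubic convolution with the Catmull–Rom
   parameter a = −0.5 (the most common "bicubic" convention; a = −0.75 is
   available via `bicubic_a`), half-pixel-centered grids, and
   clamp-to-edge taps. Weights are renormalized per output row so constants
   are exact fixed points. The output is re-symmetrized via
   $(M+M^\top)/2$ because resampling can introduce ~10⁻¹² asymmetry.
3. **Gaussian smoothing** with a 3×3, σ = 0.5 kernel under replicate
   padding. The kernel is normalized to unit sum, so smoothing preserves
   the overall count scale, maps constants to themselves, and never
   exceeds the input's min/max (convex combination).
4. **Dissipative diffusion** $B = \exp(-A''/\Sigma A'')$ where the
   normalizing sum runs over the full matrix including the diagonal. The
   time −1 exponential penalizes indirect transitive paths, acting as a
   sharpening (high-pass) operator on domain boundaries. An all-zero map
   has no scale; it maps to $\exp(0)=I$, keeping the ensemble rectangular.
   Fast mode truncates the Taylor series at `taylor_order = 10`; since
   $\|A''/\Sigma A''\| \le 1$, 10 terms give ~3 × 10⁻⁸ accuracy.

All stages map symmetric inputs to symmetric outputs (within 10⁻¹⁰); the
maps are mutually independent, so the loop parallelizes trivially with
results identical to serial execution.

## Superdiagonal features

For offsets $w = 0 \ldots \zeta$ the $w$-th superdiagonals of a cell's $b$
imputed maps are concatenated in chromosome order (length $b(r-w)$),
z-scored with the sample standard deviation (denominator $b(r-w)-1$), and
trinarized: $f_\alpha = \mathrm{sgn}(e'_\alpha - e'_{\alpha+1})$, with
sgn(0) = 0 so ties map to 0. The final entry is $\mathrm{sgn}(e'_{\text{last}})$
so the vector is genuinely ternary; `literal_last_entry=True` stores the
raw $e'_{\text{last}}$ instead for users who want the alternative
convention. A constant band (zero variance) z-scores to the zero vector
rather than NaN — it simply contributes no discriminative signal.

Cosine distances are computed per offset over both feature sets; a
zero-magnitude vector is assigned distance 1 to any nonzero vector
(maximal ignorance) and 0 to another zero vector, keeping matrices finite,
symmetric, and zero-diagonal. The combined matrix
$K^w_{ij} = e^{D'^w_{ij}+D^w_{ij}}$ has unit diagonal and entries in
$[1, e^4]$.

## Reduction cascade and spectral embedding

Per offset, $K^w$ (diagonal zeroed — MDS requires zero self-dissimilarity,
and nonmetric MDS is tolerant to monotone changes off-diagonal) is embedded
by nonmetric MDS into $p = 30$ dimensions and reduced by PCA (centered, not
re-scaled: MDS axes are already commensurate) to $q = 5$. PCA is fit per
offset independently, matching the per-offset construction of the blocks.
Nonmetric MDS is SMACOF majorization of normalized stress, initialized from
the classical (Torgerson) solution of the same matrix, `max_iter = 300`,
relative tolerance 10⁻⁶, single start — deterministic by construction.
When $a \le p$ the target dimension is lowered to $a-1$ with a warning.

Blocks concatenate into $R$ ($a \times q(\zeta+1)$), softmax-normalized
over cells within each feature column (max-subtraction for overflow
safety), followed by L1 distances $S$ and a second MDS to the latent
dimension $\epsilon = 5$, giving $V$. Fast mode uses classical MDS in both
places; classical MDS is exact on Euclidean dissimilarities, which is the
correctness anchor the tests verify by Procrustes residual.

The spectral step builds $A_{ij} = e^{-Z_{ij}^2}$ from pairwise latent
distances, keeps each point's $k = \lceil \ln a \rceil$ nearest neighbors
(natural log, self excluded), symmetrizes by union (max) — union preserves
connectivity on sparse graphs — and solves the Shi–Malik generalized
eigenproblem through the symmetric normalized Laplacian with
back-transformation $u = D^{-1/2}v$, which is numerically stable for
near-zero eigenvalues. $C$ holds the eigenvectors of the $l-1$ smallest
eigenvalues after the first, ascending; when the graph is disconnected the
extra zero-eigenvalue eigenvectors are component indicators and are
deliberately kept. Eigenvector signs are fixed by making each column's
largest-magnitude entry positive.

Either $C$ (default) or $V$ feeds k-means++ (`n_init = 10` restarts, 300
iterations, tolerance 10⁻⁴).

## Metrics

ARI uses exact integer binomial arithmetic on the contingency table, so it
is exact at any ensemble size. NMI uses log base 2 with geometric-mean
normalization and the convention 0·log 0 = 0. Degenerate cases (zero
denominator, single-cluster partition) return 0 with a warning. The test
suite verifies ARI against an independent pair-counting formulation and
both metrics against scikit-learn.

Scoring repeats clustering with seeds derived from the master seed via
`SeedSequence` over (seed, stage-name CRC, repeat index) — stable across
processes, unlike salted string hashing — and reports mean ± sd over
10 repeats by default.

## Synthetic data

The generator plants cell-type structure in a background that mimics the
two dominant features of real single-cell maps:

* contact probability decays as $(1+|i-j|)^{-\gamma}$ with γ = 1, the
  canonical contact-decay exponent at Mb scale;
* TAD-like blocks multiply within-block contact probability by a fixed
  enrichment (8×); cell types differ only by shifting internal block
  boundaries (type $t$ shifts by $t \cdot$ `boundary_shift` bins), mirroring
  the biological observation that domain boundaries vary between cell
  types.

Each cell samples exactly `contacts_per_cell` contacts multinomially —
first across chromosomes (proportional to squared bin count), then across
the upper triangle of its (noise-mixed) type profile — so per-cell count
conservation is exact and the coverage filters are precisely controllable
in tests. `contacts_per_cell` is a genome-wide total, as in real QC
thresholds: spread over a genome-like chromosome complement, 5k contacts
reproduces the ≥95% off-diagonal sparsity of real 1 Mb maps.

What the generator does **not** model: polymer physics, A/B compartments,
loops, cell-cycle structure, coverage biases, or trans contacts. Passing
the end-to-end recovery test therefore demonstrates that the pipeline
recovers planted domain-boundary differences under realistic sparsity — it
does not certify accuracy on any real dataset.

## Problem sizes used in validation

The end-to-end recovery check uses a = 120 cells, l = 3 balanced types,
b = 4 chromosomes of 60/55/50/45 bins (r = 52), 100k contacts/cell,
boundary shift 4 bins, no within-type noise — a strong-signal regime in
which mean ARI ≥ 0.9 is required (observed: 1.0), with the no-signal
control (shift 0) required to score at chance. Determinism is checked by
running the identical config twice end-to-end and comparing V, C, and
labels bitwise. Metric nulls use 10,000 random labelings of 100 cells.

## Known limitations

* Chromosome sizes are inferred from the largest observed bin index when a
  container carries no explicit sizes, which can undersize a chromosome if
  its telomeric bins have no contacts; pass `chrom_sizes` to pin them.
* Nonmetric MDS minimizes a non-convex stress; determinism is achieved by
  fixed initialization, not global optimality.
* The ζ–ε sweep caches per-offset blocks, so its per-cell scores are only
  comparable across the grid when the cell count is unchanged.
* `n_labels` must be supplied (or inferable from labels); the pipeline
  does not estimate the number of clusters.
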