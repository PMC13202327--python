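"""End-to-end orchestration: read -> filter -> impute -> band features ->
manifold -> cluster -> score, plus the hyperparameter-sweep and
chromosome-subsampling experiment drivers.

Every run is driven by a :class:`RunConfig` that is serializable to YAML; a
run always writes its resolved config next to its outputs so any result can
be reproduced bitwise from that file alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts_io
from .contacts_io import CellEnsemble
from .imputation import ImputationParams, impute_ensemble, common_dimension
from .diagonal_features import DiagonalDistanceSet, features_for_all_offsets
from .manifold import (EmbeddingBundle, ReductionParams, build_embeddings,
                       embed_latent, l1_distance, reduce_offset,
                       spectral_embed, stack_and_normalize)
from .clustering_metrics import (ClusterResult, ScoreSummary, derive_seed,
                                 kmeans_pp, score_embedding)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_scuddo", "run_on_ensemble",
           "sweep_hyperparams", "chromosome_curve", "recovery_experiment"]


@dataclass
class RunConfig:
    """Complete, serializable description of one run."""

    # inputs
    input_path: str = ""
    input_format: str = "scool"  # scool | cool | pairs | triplets
    bin_size: int = 1_000_000
    labels_path: str | None = None
    output_dir: str = "scuddo_out"
    # filtering
    min_total_contacts: int = 5000
    max_empty_frac: float = 0.10
    apply_filters: bool = True
    # imputation
    kernel_size: int = 3
    sigma: float = 0.5
    neumann_order: int = 8
    taylor_order: int = 10
    bicubic_a: float = -0.5
    # reduction
    p: int = 30
    q: int = 5
    zeta: int = 25
    epsilon: int = 5
    n_labels: int | None = None  # inferred from labels when absent
    # clustering / scoring
    repeats: int = 10
    kmeans_n_init: int = 10
    embedding_choice: str = "C"  # C | V
    # global
    fast_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_choice not in ("C", "V"):
            raise ValueError("embedding_choice must be 'C' or 'V'")

    def imputation_params(self) -> ImputationParams:
        return ImputationParams(kernel_size=self.kernel_size,
                                sigma=self.sigma,
                                fast_mode=self.fast_mode,
                                neumann_order=self.neumann_order,
                                taylor_order=self.taylor_order,
                                bicubic_a=self.bicubic_a)

    def reduction_params(self, n_labels: int) -> ReductionParams:
        return ReductionParams(
            p=self.p, q=self.q, zeta=self.zeta, epsilon=self.epsilon,
            n_labels_l=n_labels,
            mds_mode="classical" if self.fast_mode else "nonmetric",
            seed=derive_seed(self.seed, "mds"))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunResult:
    """In-memory products of one run."""

    ensemble: CellEnsemble
    r: int
    distance_sets: list[DiagonalDistanceSet]
    bundle: EmbeddingBundle
    cluster: ClusterResult
    scores: ScoreSummary | None


def _resolve_labels(config: RunConfig, ensemble: CellEnsemble) -> CellEnsemble:
    if config.labels_path:
        df = pd.read_csv(config.labels_path, sep="\t", header=None,
                         names=["cell_id", "label"], dtype=str,
                         comment="#")
        labels = dict(zip(df.cell_id, df.label))
        ensemble = CellEnsemble(ensemble.cells, ensemble.chroms,
                                ensemble.maps,
                                {c: labels[c] for c in ensemble.cells},
                                ensemble.bin_size)
    return ensemble


def _n_labels(config: RunConfig, ensemble: CellEnsemble) -> int:
    if config.n_labels is not None:
        return config.n_labels
    if ensemble.labels is not None:
        return len(set(ensemble.labels.values()))
    raise ValueError("n_labels not set and no ground-truth labels available")


def prepare_ensemble(config: RunConfig) -> CellEnsemble:
    """Read and filter the input according to the config."""
    ensemble = contacts_io.read_contacts(config.input_path,
                                         config.input_format,
                                         config.bin_size)
    ensemble = _resolve_labels(config, ensemble)
    if config.apply_filters:
        ensemble = contacts_io.drop_empty_chromosomes(
            ensemble, config.max_empty_frac)
        ensemble = contacts_io.filter_cells(
            ensemble, config.min_total_contacts)
    return ensemble


def run_on_ensemble(ensemble: CellEnsemble, config: RunConfig) -> RunResult:
    """Run imputation through scoring on an in-memory ensemble."""
    t0 = time.perf_counter()
    n_labels = _n_labels(config, ensemble)
    r = common_dimension(ensemble)
    zeta = min(config.zeta, r - 2)
    if zeta < config.zeta:
        logger.warning("zeta lowered from %d to %d (r=%d)",
                       config.zeta, zeta, r)
    logger.info("run: a=%d cells, b=%d chromosomes, r=%d, l=%d",
                ensemble.n_cells, ensemble.n_chroms, r, n_labels)

    imputed = impute_ensemble(ensemble, config.imputation_params())
    t1 = time.perf_counter()
    logger.info("imputation: %.2fs", t1 - t0)

    dsets = features_for_all_offsets(imputed, ensemble.cells,
                                     ensemble.chroms, zeta)
    t2 = time.perf_counter()
    logger.info("diagonal features: %.2fs", t2 - t1)

    rparams = config.reduction_params(n_labels)
    bundle = build_embeddings(dsets, rparams)
    t3 = time.perf_counter()
    logger.info("manifold: %.2fs", t3 - t2)

    target = bundle.C if config.embedding_choice == "C" else bundle.V
    cluster = kmeans_pp(target, n_labels, n_init=config.kmeans_n_init,
                        seed=derive_seed(config.seed, "kmeans", 0))
    scores = None
    if ensemble.labels is not None:
        scores = score_embedding(target, ensemble.label_vector(), n_labels,
                                 repeats=config.repeats, seed=config.seed,
                                 n_init=config.kmeans_n_init)
        logger.info("scores: ARI %.3f +/- %.3f, NMI %.3f +/- %.3f",
                    scores.mean_ari, scores.sd_ari, scores.mean_nmi,
                    scores.sd_nmi)
    logger.info("clustering: %.2fs", time.perf_counter() - t3)
    return RunResult(ensemble, r, dsets, bundle, cluster, scores)


def _write_embedding_tsv(path: Path, cells: list[str], M: np.ndarray,
                         prefix: str) -> None:
    df = pd.DataFrame(M, columns=[f"{prefix}{j}" for j in range(M.shape[1])])
    df.insert(0, "cell_id", cells)
    df.to_csv(path, sep="\t", index=False)


def write_outputs(result: RunResult, config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = result.ensemble.cells
    _write_embedding_tsv(out / "V.tsv", cells, result.bundle.V, "V")
    _write_embedding_tsv(out / "C.tsv", cells, result.bundle.C, "C")
    pd.DataFrame({"cell_id": cells,
                  "label": result.cluster.labels}).to_csv(
        out / "predicted_labels.tsv", sep="\t", index=False, header=False)
    if result.scores is not None:
        with open(out / "scores.json", "w") as fh:
            json.dump(result.scores.to_dict(), fh, indent=2)
    config.to_yaml(out / "config.yaml")
    return out


def run_scuddo(config: RunConfig) -> RunResult:
    """Full pipeline from files on disk; writes all outputs."""
    ensemble = prepare_ensemble(config)
    result = run_on_ensemble(ensemble, config)
    write_outputs(result, config)
    return result


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def sweep_hyperparams(ensemble: CellEnsemble, config: RunConfig,
                      zeta_grid: list[int],
                      epsilon_grid: list[int]) -> pd.DataFrame:
    """ARI/NMI over a (zeta, epsilon) grid.

    Imputation and the per-offset distance sets (plus their MDS+PCA blocks)
    are computed once at the largest zeta and sliced per grid cell, so the
    sweep only reruns the cascade stages that actually depend on zeta and
    epsilon.  A failed cell is recorded with NaN scores, not an abort.
    """
    n_labels = _n_labels(config, ensemble)
    r = common_dimension(ensemble)
    zmax = min(max(zeta_grid), r - 2)
    imputed = impute_ensemble(ensemble, config.imputation_params())
    dsets = features_for_all_offsets(imputed, ensemble.cells,
                                     ensemble.chroms, zmax)
    rparams = config.reduction_params(n_labels)
    U_blocks = [reduce_offset(ds.K, rparams) for ds in dsets]
    truth = ensemble.label_vector() if ensemble.labels else None
    rows = []
    for zeta in zeta_grid:
        z = min(zeta, zmax)
        for eps in epsilon_grid:
            try:
                _, R_soft = stack_and_normalize(U_blocks[:z + 1])
                S = l1_distance(R_soft)
                rp = dataclasses.replace(rparams, zeta=z, epsilon=eps)
                V = embed_latent(S, rp)
                C = spectral_embed(V, n_labels)
                target = C if config.embedding_choice == "C" else V
                if truth is None:
                    raise ValueError("sweep scoring requires labels")
                sc = score_embedding(target, truth, n_labels,
                                     repeats=config.repeats,
                                     seed=config.seed,
                                     n_init=config.kmeans_n_init)
                rows.append({"zeta": zeta, "epsilon": eps,
                             "mean_ari": sc.mean_ari, "sd_ari": sc.sd_ari,
                             "mean_nmi": sc.mean_nmi, "sd_nmi": sc.sd_nmi})
            except Exception as exc:  # record, do not abort the grid
                logger.error("sweep cell (zeta=%d, eps=%d) failed: %s",
                             zeta, eps, exc)
                rows.append({"zeta": zeta, "epsilon": eps,
                             "mean_ari": np.nan, "sd_ari": np.nan,
                             "mean_nmi": np.nan, "sd_nmi": np.nan})
    return pd.DataFrame(rows)


def chromosome_curve(ensemble: CellEnsemble, config: RunConfig,
                     b_values: list[int]) -> pd.DataFrame:
    """ARI/NMI versus the number of (natural-order) chromosomes used."""
    rows = []
    for b in b_values:
        sub = contacts_io.restrict_chromosomes(ensemble, b)
        res = run_on_ensemble(sub, config)
        sc = res.scores
        if sc is None:
            raise ValueError("chromosome curve requires labels")
        rows.append({"b": b, "mean_ari": sc.mean_ari, "sd_ari": sc.sd_ari,
                     "mean_nmi": sc.mean_nmi, "sd_nmi": sc.sd_nmi})
    return pd.DataFrame(rows)


def recovery_experiment(spec, config: RunConfig | None = None) -> ScoreSummary:
    """Sample a synthetic ensemble, run the full pipeline, score the planted
    labels."""
    from .synthetic_data import sample_ensemble

    config = config or RunConfig()
    ensemble = sample_ensemble(spec)
    if config.apply_filters:
        ensemble = contacts_io.drop_empty_chromosomes(
            ensemble, config.max_empty_frac)
        ensemble = contacts_io.filter_cells(
            ensemble, config.min_total_contacts)
    result = run_on_ensemble(ensemble, config)
    assert result.scores is not None
    return result.scores
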