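"""Reading, re-binning, assembly and quality filtering of per-cell
intrachromosomal Hi-C contact matrices.

A single-cell Hi-C experiment yields, for each cell, one symmetric matrix of
nonnegative integer contact counts per chromosome.  At 1 Mb resolution these
matrices are extremely sparse -- most off-diagonal bins are zero -- so the
filtering rules here (minimum per-cell contact totals, dropping chromosomes
that are empty in too many cells) are an essential part of the pipeline, not
cosmetics.

Supported on-disk dialects:

``triplets``
    One whitespace-delimited text file per cell with records
    ``chrom<TAB>bin_i<TAB>bin_j<TAB>count`` (0-based bin indices).
``pairs``
    4DN-style pairs text, one file per cell; columns ``chrom1 pos1 chrom2
    pos2`` are located via the ``#columns:`` header or assumed at the
    conventional positions (readID chr1 pos1 chr2 pos2 ...).  Positions are
    binned by ``floor(pos / bin_size)``.
``cool`` / ``scool``
    HDF5 single-cell cooler layout (bins + pixels tables); read and written
    through :mod:`h5py`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "CellEnsemble",
    "read_contacts",
    "filter_cells",
    "drop_empty_chromosomes",
    "restrict_chromosomes",
    "write_scool",
    "write_filter_report",
    "natural_chrom_sort",
]

DEFAULT_BIN_SIZE = 1_000_000


class FormatError(ValueError):
    """Raised when an input file does not parse under the declared dialect."""


class EmptyEnsembleError(ValueError):
    """Raised when filtering removes every cell or every chromosome."""


def _natural_key(chrom: str) -> tuple:
    """Sort key putting chr1 < chr2 < ... < chr10 < ... < chr19 < chrX < chrY."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def natural_chrom_sort(chroms: Iterable[str]) -> list[str]:
    """Return chromosome names in natural order (chr1, chr2, ..., chr19, chrX)."""
    return sorted(chroms, key=_natural_key)


_SEX_RE = re.compile(r"^(chr)?[XYxy]$")


def is_autosome(chrom: str) -> bool:
    return not _SEX_RE.match(chrom)


@dataclass(frozen=True)
class ContactMap:
    """One cell's contact matrix for a single chromosome.

    The matrix is square, exactly symmetric, and holds nonnegative integer
    counts; its dimension depends only on the chromosome within one ensemble.
    """

    cell_id: str
    chrom_id: str
    matrix: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact matrix must be square, got {m.shape}")
        if (m < 0).any():
            raise ValueError("contact matrix has negative entries")
        if not np.array_equal(m, m.T):
            raise ValueError("contact matrix is not symmetric")
        object.__setattr__(self, "matrix", m.astype(np.int64, copy=False))

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def offdiag_sum(self) -> int:
        """Sum of counts over all strictly off-diagonal entries (both triangles)."""
        return int(self.matrix.sum() - np.trace(self.matrix))

    def is_empty(self) -> bool:
        return not self.matrix.any()


@dataclass
class CellEnsemble:
    """The a x b grid of per-cell, per-chromosome contact maps.

    ``cells`` and ``chroms`` fix the ordering used everywhere downstream;
    ``maps`` holds one :class:`ContactMap` per (cell, chromosome) pair.
    ``labels`` optionally carries ground-truth cell-type labels.
    """

    cells: list[str]
    chroms: list[str]
    maps: dict[tuple[str, str], ContactMap]
    labels: dict[str, str] | None = None
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        for cell in self.cells:
            for chrom in self.chroms:
                if (cell, chrom) not in self.maps:
                    raise ValueError(f"missing map for ({cell}, {chrom})")
        dims: dict[str, int] = {}
        for (_, chrom), cmap in self.maps.items():
            if chrom in dims and dims[chrom] != cmap.n_bins:
                raise ValueError(f"inconsistent dimension for {chrom}")
            dims[chrom] = cmap.n_bins
        if self.labels is not None:
            missing = [c for c in self.cells if c not in self.labels]
            if missing:
                raise ValueError(f"cells without labels: {missing[:5]}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_chroms(self) -> int:
        return len(self.chroms)

    def chrom_bins(self, chrom: str) -> int:
        return self.maps[(self.cells[0], chrom)].n_bins

    def get(self, cell: str, chrom: str) -> ContactMap:
        return self.maps[(cell, chrom)]

    def label_vector(self) -> list[str]:
        if self.labels is None:
            raise ValueError("ensemble carries no labels")
        return [self.labels[c] for c in self.cells]

    def subset(
        self, cells: list[str] | None = None, chroms: list[str] | None = None
    ) -> "CellEnsemble":
        cells = list(self.cells) if cells is None else list(cells)
        chroms = list(self.chroms) if chroms is None else list(chroms)
        maps = {
            (s, k): self.maps[(s, k)] for s in cells for k in chroms
        }
        labels = None
        if self.labels is not None:
            labels = {c: self.labels[c] for c in cells}
        return CellEnsemble(cells, chroms, maps, labels, self.bin_size)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _symmetrize_counts(counts: dict[tuple[int, int], int], n: int,
                       context: str) -> np.ndarray:
    """Assemble a symmetric matrix from (i, j) -> count records.

    Records are accumulated into the upper triangle; if both (i, j) and (j, i)
    appear they are summed (mirrored storage is common in pairs dumps) and a
    warning is logged when the two triangles disagree.
    """
    upper: dict[tuple[int, int], int] = {}
    for (i, j), c in counts.items():
        key = (i, j) if i <= j else (j, i)
        upper[key] = upper.get(key, 0) + c
    mat = np.zeros((n, n), dtype=np.int64)
    asym = any(
        i != j and (j, i) in counts and counts[(j, i)] != c
        for (i, j), c in counts.items()
    )
    if asym:
        logger.warning("asymmetric triplet input in %s; symmetrizing by "
                       "summing upper+lower triangles", context)
    for (i, j), c in upper.items():
        mat[i, j] = c
        mat[j, i] = c
    return mat


def _rebin_indices(idx: np.ndarray, src_bin: int, dst_bin: int) -> np.ndarray:
    """Map bin indices at src_bin resolution onto dst_bin resolution."""
    if dst_bin % src_bin:
        raise ValueError(
            f"target bin size {dst_bin} is not a multiple of source {src_bin}")
    return idx * src_bin // dst_bin


def _read_triplets_file(path: Path, bin_size: int,
                        src_bin_size: int | None) -> dict[str, dict[tuple[int, int], int]]:
    per_chrom: dict[str, dict[tuple[int, int], int]] = {}
    src = src_bin_size or bin_size
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 fields "
                    f"(chrom bin_i bin_j count), got {len(parts)}")
            chrom, si, sj, sc = parts
            try:
                i, j, c = int(si), int(sj), int(sc)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if i < 0 or j < 0 or c < 0:
                raise FormatError(f"{path}:{lineno}: negative bin index or count")
            if src != bin_size:
                i = int(_rebin_indices(np.array([i]), src, bin_size)[0])
                j = int(_rebin_indices(np.array([j]), src, bin_size)[0])
            d = per_chrom.setdefault(chrom, {})
            d[(i, j)] = d.get((i, j), 0) + c
    return per_chrom


_PAIRS_DEFAULT_COLS = {"chrom1": 1, "pos1": 2, "chrom2": 3, "pos2": 4}


def _read_pairs_file(path: Path, bin_size: int) -> dict[str, dict[tuple[int, int], int]]:
    cols = dict(_PAIRS_DEFAULT_COLS)
    per_chrom: dict[str, dict[tuple[int, int], int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("#columns:"):
                    names = line.split(":", 1)[1].split()
                    for want in cols:
                        if want in names:
                            cols[want] = names.index(want)
                continue
            if not line.strip():
                continue
            parts = line.split()
            try:
                c1 = parts[cols["chrom1"]]
                p1 = int(parts[cols["pos1"]])
                c2 = parts[cols["chrom2"]]
                p2 = int(parts[cols["pos2"]])
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"{path}:{lineno}: cannot parse pairs record") from exc
            if c1 != c2:
                continue  # trans contacts are out of scope
            i, j = p1 // bin_size, p2 // bin_size
            d = per_chrom.setdefault(c1, {})
            d[(i, j)] = d.get((i, j), 0) + 1
    return per_chrom


def _assemble(per_cell: Mapping[str, Mapping[str, Mapping[tuple[int, int], int]]],
              bin_size: int,
              chrom_sizes: Mapping[str, int] | None = None,
              include_sex: bool = False) -> CellEnsemble:
    """Build a rectangular ensemble from per-cell sparse records.

    Chromosome dimensions are the supplied ``chrom_sizes`` (in bins) or, when
    absent, inferred as max bin index + 1 across all cells.
    """
    cells = sorted(per_cell)
    all_chroms = sorted({k for recs in per_cell.values() for k in recs},
                        key=_natural_key)
    if not include_sex:
        all_chroms = [c for c in all_chroms if is_autosome(c)]
    if not all_chroms:
        raise EmptyEnsembleError("no chromosomes found in input")
    sizes: dict[str, int] = {}
    for chrom in all_chroms:
        if chrom_sizes and chrom in chrom_sizes:
            sizes[chrom] = int(chrom_sizes[chrom])
        else:
            mx = 0
            for recs in per_cell.values():
                for (i, j) in recs.get(chrom, {}):
                    mx = max(mx, i, j)
            sizes[chrom] = mx + 1
    maps = {}
    for cell in cells:
        for chrom in all_chroms:
            recs = per_cell[cell].get(chrom, {})
            mat = _symmetrize_counts(recs, sizes[chrom], f"{cell}/{chrom}")
            maps[(cell, chrom)] = ContactMap(cell, chrom, mat, bin_size)
    return CellEnsemble(cells, all_chroms, maps, None, bin_size)


def _read_cool_group(grp: h5py.Group, cell_id: str,
                     bin_size: int) -> tuple[dict, dict[str, int], int]:
    """Read one cooler group (bins + pixels) into per-chrom sparse records."""
    chrom_names = [c.decode() if isinstance(c, bytes) else str(c)
                   for c in grp["chroms/name"][:]]
    bins_chrom = grp["bins/chrom"][:]
    bins_start = grp["bins/start"][:]
    src_bin = int(grp["bins/end"][0] - grp["bins/start"][0])
    bin1 = grp["pixels/bin1_id"][:]
    bin2 = grp["pixels/bin2_id"][:]
    count = grp["pixels/count"][:]
    per_chrom: dict[str, dict[tuple[int, int], int]] = {}
    chrom_of = np.asarray(bins_chrom)
    local = bins_start // src_bin
    if src_bin != bin_size:
        local = _rebin_indices(local.astype(np.int64), src_bin, bin_size)
    sizes: dict[str, int] = {}
    for ci, name in enumerate(chrom_names):
        nb = int(local[chrom_of == ci].max()) + 1 if (chrom_of == ci).any() else 0
        sizes[name] = nb
    for b1, b2, c in zip(bin1, bin2, count):
        c1, c2 = int(chrom_of[b1]), int(chrom_of[b2])
        if c1 != c2:
            continue
        name = chrom_names[c1]
        i, j = int(local[b1]), int(local[b2])
        d = per_chrom.setdefault(name, {})
        d[(i, j)] = d.get((i, j), 0) + int(c)
    return per_chrom, sizes, src_bin


def read_contacts(path: str | Path, format: str,
                  bin_size: int = DEFAULT_BIN_SIZE,
                  src_bin_size: int | None = None,
                  chrom_sizes: Mapping[str, int] | None = None,
                  include_sex: bool = False) -> CellEnsemble:
    """Read per-cell contact matrices into a :class:`CellEnsemble`.

    Parameters
    ----------
    path
        File (``cool``/``scool``/single-cell ``triplets``/``pairs``) or a
        directory of per-cell ``triplets``/``pairs`` files (the stem of each
        file becomes the cell id).
    format
        One of ``scool``, ``cool``, ``pairs``, ``triplets``.
    bin_size
        Target resolution in base pairs; higher-resolution inputs are
        aggregated by summing counts into coarser bins.
    src_bin_size
        Bin size of triplet input indices (defaults to ``bin_size``, i.e. no
        re-binning).
    chrom_sizes
        Optional chromosome sizes in *bins* at the target resolution; if
        absent, sizes are inferred from the largest observed bin index.
    include_sex
        Keep chrX/chrY (dropped by default; clustering benchmarks run on
        autosomes).
    """
    path = Path(path)
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "scool":
        per_cell: dict[str, dict] = {}
        sizes_all: dict[str, int] = {}
        with h5py.File(path, "r") as f:
            if "cells" not in f:
                raise FormatError(f"{path}: no /cells group; not an .scool file")
            for cell_id in sorted(f["cells"]):
                recs, sizes, _ = _read_cool_group(f["cells"][cell_id],
                                                  cell_id, bin_size)
                per_cell[cell_id] = recs
                for k, v in sizes.items():
                    sizes_all[k] = max(sizes_all.get(k, 0), v)
        merged = dict(sizes_all)
        if chrom_sizes:
            merged.update(chrom_sizes)
        return _assemble(per_cell, bin_size, merged, include_sex)
    if format == "cool":
        with h5py.File(path, "r") as f:
            recs, sizes, _ = _read_cool_group(f, path.stem, bin_size)
        merged = dict(sizes)
        if chrom_sizes:
            merged.update(chrom_sizes)
        return _assemble({path.stem: recs}, bin_size, merged, include_sex)
    if format in ("triplets", "pairs"):
        files = sorted(path.iterdir()) if path.is_dir() else [path]
        files = [p for p in files if p.is_file()]
        if not files:
            raise FormatError(f"{path}: no input files found")
        per_cell = {}
        for p in files:
            if format == "triplets":
                per_cell[p.stem] = _read_triplets_file(p, bin_size, src_bin_size)
            else:
                per_cell[p.stem] = _read_pairs_file(p, bin_size)
        return _assemble(per_cell, bin_size, chrom_sizes, include_sex)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_scool(ensemble: CellEnsemble, path: str | Path) -> None:
    """Write the ensemble in the single-cell cooler HDF5 layout."""
    path = Path(path)
    chroms = ensemble.chroms
    sizes = [ensemble.chrom_bins(k) for k in chroms]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::SCOOL"
        f.attrs["bin-size"] = ensemble.bin_size
        cells_grp = f.create_group("cells")
        for cell in ensemble.cells:
            g = cells_grp.create_group(cell)
            g.create_dataset("chroms/name",
                             data=np.array(chroms, dtype="S32"))
            g.create_dataset("chroms/length",
                             data=np.array(sizes) * ensemble.bin_size)
            bc, bs, be = [], [], []
            for ci, (k, nb) in enumerate(zip(chroms, sizes)):
                bc.extend([ci] * nb)
                starts = np.arange(nb) * ensemble.bin_size
                bs.extend(starts)
                be.extend(starts + ensemble.bin_size)
            g.create_dataset("bins/chrom", data=np.array(bc, dtype=np.int32))
            g.create_dataset("bins/start", data=np.array(bs, dtype=np.int64))
            g.create_dataset("bins/end", data=np.array(be, dtype=np.int64))
            b1, b2, cnt = [], [], []
            for ci, k in enumerate(chroms):
                mat = ensemble.get(cell, k).matrix
                iu, ju = np.nonzero(np.triu(mat))
                b1.extend(iu + offsets[ci])
                b2.extend(ju + offsets[ci])
                cnt.extend(mat[iu, ju])
            g.create_dataset("pixels/bin1_id", data=np.array(b1, dtype=np.int64))
            g.create_dataset("pixels/bin2_id", data=np.array(b2, dtype=np.int64))
            g.create_dataset("pixels/count", data=np.array(cnt, dtype=np.int64))


def write_filter_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def drop_empty_chromosomes(ensemble: CellEnsemble,
                           max_empty_frac: float = 0.10) -> CellEnsemble:
    """Drop any chromosome whose map is all-zero in more than
    ``max_empty_frac`` of cells (strictly greater; exactly the threshold is
    kept)."""
    if ensemble.n_cells == 0:
        raise EmptyEnsembleError("empty ensemble")
    keep = []
    for chrom in ensemble.chroms:
        n_empty = sum(ensemble.get(c, chrom).is_empty() for c in ensemble.cells)
        if n_empty / ensemble.n_cells > max_empty_frac:
            logger.info("dropping %s: %d/%d empty maps", chrom, n_empty,
                        ensemble.n_cells)
        else:
            keep.append(chrom)
    if not keep:
        raise EmptyEnsembleError("all chromosomes dropped by empty-map filter")
    return ensemble.subset(chroms=keep)


def filter_cells(ensemble: CellEnsemble, min_total: int = 5000,
                 count_entries: bool = False,
                 report: list | None = None) -> CellEnsemble:
    """Remove low-coverage cells.

    A cell is removed when (a) its summed off-diagonal counts over all
    retained chromosomes fall below ``min_total``, or (b) any single
    chromosome of ``x`` bins has an off-diagonal contact sum below ``x``.
    With ``count_entries=True`` rule (a) counts distinct nonzero off-diagonal
    entries instead of summed counts.
    """
    if ensemble.n_cells == 0:
        raise EmptyEnsembleError("empty ensemble")
    keep = []
    for cell in ensemble.cells:
        total = 0
        chrom_fail = None
        for chrom in ensemble.chroms:
            cmap = ensemble.get(cell, chrom)
            if count_entries:
                off = cmap.matrix.copy()
                np.fill_diagonal(off, 0)
                total += int((off > 0).sum())
            else:
                total += cmap.offdiag_sum()
            if cmap.offdiag_sum() < cmap.n_bins:
                chrom_fail = chrom
        if chrom_fail is not None:
            status = ("removed", f"chromosome {chrom_fail} off-diagonal sum "
                                 f"below its bin count")
        elif total < min_total:
            status = ("removed", f"total off-diagonal contacts {total} < "
                                 f"{min_total}")
        else:
            status = ("retained", "")
            keep.append(cell)
        if report is not None:
            report.append({"cell_id": cell, "status": status[0],
                           "reason": status[1]})
    if not keep:
        raise EmptyEnsembleError("all cells removed by coverage filter")
    return ensemble.subset(cells=keep)


def restrict_chromosomes(ensemble: CellEnsemble, b_keep: int) -> CellEnsemble:
    """Keep only the first ``b_keep`` chromosomes in natural order."""
    if not 1 <= b_keep <= ensemble.n_chroms:
        raise ValueError(
            f"b_keep must be in [1, {ensemble.n_chroms}], got {b_keep}")
    ordered = natural_chrom_sort(ensemble.chroms)
    return ensemble.subset(chroms=ordered[:b_keep])
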