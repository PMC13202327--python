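"""I/O, re-binning and quality filtering of contact-map ensembles."""

import numpy as np
import pytest

from scuddo import contacts_io
from scuddo.contacts_io import (EmptyEnsembleError, drop_empty_chromosomes,
                                filter_cells, natural_chrom_sort,
                                read_contacts, restrict_chromosomes,
                                write_scool)

from conftest import make_ensemble


def _write_triplets(path, records):
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(map(str, rec)) + "\n")


class TestReaders:
    def test_single_triplet_is_mirrored(self, tmp_path):
        f = tmp_path / "cellA.tsv"
        _write_triplets(f, [("chr1", 3, 7, 2)])
        ens = read_contacts(f, "triplets")
        mat = ens.get("cellA", "chr1").matrix
        assert mat[3, 7] == 2 and mat[7, 3] == 2
        assert mat.sum() == 4

    def test_contradictory_triplets_summed_into_both(self, tmp_path, caplog):
        f = tmp_path / "cellA.tsv"
        _write_triplets(f, [("chr1", 0, 1, 2), ("chr1", 1, 0, 5)])
        ens = read_contacts(f, "triplets")
        mat = ens.get("cellA", "chr1").matrix
        assert mat[0, 1] == 7 and mat[1, 0] == 7

    def test_rebinning_aggregates_and_conserves_counts(self, tmp_path):
        # bins 0-9 at 100 kb all land in bin 0 at 1 Mb; counts sum
        f = tmp_path / "cellA.tsv"
        recs = [("chr1", i, i, 1) for i in range(10)]
        recs += [("chr1", 3, 17, 4)]
        _write_triplets(f, recs)
        ens = read_contacts(f, "triplets", bin_size=1_000_000,
                            src_bin_size=100_000)
        mat = ens.get("cellA", "chr1").matrix
        assert mat[0, 0] == 10
        assert mat[0, 1] == 4 and mat[1, 0] == 4
        total_100kb = 10 + 2 * 4  # symmetric total at source resolution
        assert mat.sum() == total_100kb

    def test_pairs_format_bins_positions_and_drops_trans(self, tmp_path):
        f = tmp_path / "cellB.pairs"
        f.write_text(
            "## pairs format v1.0\n"
            "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n"
            "r1\tchr1\t1500000\tchr1\t3500000\t+\t-\n"
            "r2\tchr1\t100\tchr2\t100\t+\t-\n"  # trans: discarded
            "r3\tchr2\t2000001\tchr2\t2999999\t+\t-\n")
        ens = read_contacts(f, "pairs", bin_size=1_000_000)
        assert ens.get("cellB", "chr1").matrix[1, 3] == 1
        assert ens.get("cellB", "chr2").matrix[2, 2] == 1

    def test_malformed_triplet_names_line(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("chr1\t1\t2\t3\nchr1\toops\n")
        with pytest.raises(contacts_io.FormatError, match="bad.tsv:2"):
            read_contacts(f, "triplets")

    def test_scool_round_trip(self, tmp_path, random_symmetric_counts):
        ens = make_ensemble({
            (c, k): random_symmetric_counts(6 if k == "chr1" else 4)
            for c in ("cellA", "cellB") for k in ("chr1", "chr2")})
        path = tmp_path / "ens.scool"
        write_scool(ens, path)
        back = read_contacts(path, "scool")
        assert back.cells == ens.cells and back.chroms == ens.chroms
        for key, cmap in ens.maps.items():
            np.testing.assert_array_equal(back.maps[key].matrix, cmap.matrix)

    def test_symmetry_preserved_by_all_readers(self, tmp_path, rng):
        f = tmp_path / "cellC.tsv"
        recs = [("chr1", int(i), int(j), int(c))
                for i, j, c in rng.integers(0, 8, size=(30, 3)) if c > 0]
        _write_triplets(f, recs)
        ens = read_contacts(f, "triplets")
        m = ens.get("cellC", "chr1").matrix
        np.testing.assert_array_equal(m, m.T)


def offdiag_matrix(n, off_total):
    """Symmetric n x n matrix whose strictly off-diagonal entries sum to
    off_total (which must be even: symmetry doubles every upper entry)."""
    assert off_total % 2 == 0
    m = np.zeros((n, n), dtype=np.int64)
    m[0, 1] = m[1, 0] = off_total // 2
    return m


class TestFilters:
    def test_min_total_boundary_is_strict(self):
        # removal requires total < min_total; exactly min_total is retained
        n = 10
        ens = make_ensemble({
            ("lo", "chr1"): offdiag_matrix(n, 4998),
            ("hi", "chr1"): offdiag_matrix(n, 5000)})
        out = filter_cells(ens, min_total=5000)
        assert out.cells == ["hi"]

    def test_per_chromosome_rule_removes_whole_cell(self):
        # chr1 has 50 bins; an off-diagonal sum of 48 < 50 discards the cell
        # even though its grand total is far above min_total
        n = 50
        strong = np.ones((n, n), dtype=np.int64) * 3
        ens = make_ensemble({("weak", "chr1"): offdiag_matrix(n, 48),
                             ("weak", "chr2"): strong,
                             ("good", "chr1"): strong,
                             ("good", "chr2"): strong})
        out = filter_cells(ens, min_total=10)
        assert out.cells == ["good"]

    def test_passing_ensemble_unchanged_and_idempotent(self):
        n = 20
        dense = np.ones((n, n), dtype=np.int64)
        ens = make_ensemble({(c, "chr1"): dense for c in ("a", "b")})
        out = filter_cells(ens, min_total=10)
        assert out.cells == ens.cells
        again = filter_cells(out, min_total=10)
        assert again.cells == out.cells

    def test_all_cells_removed_raises(self):
        ens = make_ensemble({("a", "chr1"): np.zeros((5, 5), dtype=int)})
        with pytest.raises(EmptyEnsembleError):
            filter_cells(ens, min_total=1)

    @pytest.mark.parametrize("n_empty,kept", [(10, True), (11, False)])
    def test_empty_chromosome_threshold_is_strict(self, n_empty, kept):
        n_cells = 100
        dense = np.ones((4, 4), dtype=np.int64)
        empty = np.zeros((4, 4), dtype=np.int64)
        data = {}
        for i in range(n_cells):
            cell = f"c{i:03d}"
            data[(cell, "chr1")] = dense
            data[(cell, "chr2")] = empty if i < n_empty else dense
        ens = make_ensemble(data)
        out = drop_empty_chromosomes(ens, max_empty_frac=0.10)
        assert ("chr2" in out.chroms) is kept

    def test_drop_empty_identity_when_no_empty_maps(self, small_ensemble):
        out = drop_empty_chromosomes(small_ensemble)
        assert out.chroms == small_ensemble.chroms
        assert out.cells == small_ensemble.cells


class TestRestrictChromosomes:
    def test_natural_order_prefix(self):
        chroms = ["chr1", "chr10", "chr2", "chr3"]
        dense = np.ones((4, 4), dtype=np.int64)
        ens = make_ensemble({("a", k): dense for k in chroms})
        out = restrict_chromosomes(ens, 3)
        assert natural_chrom_sort(out.chroms) == ["chr1", "chr2", "chr3"]

    def test_full_keep_is_identity(self, small_ensemble):
        out = restrict_chromosomes(small_ensemble, small_ensemble.n_chroms)
        assert set(out.chroms) == set(small_ensemble.chroms)

    @pytest.mark.parametrize("bad", [0, 99])
    def test_out_of_range_raises(self, small_ensemble, bad):
        with pytest.raises(ValueError):
            restrict_chromosomes(small_ensemble, bad)

    def test_natural_sort_places_two_digit_after_single(self):
        assert natural_chrom_sort(["chr11", "chr2", "chrX", "chr1"]) == [
            "chr1", "chr2", "chr11", "chrX"]
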