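"""Genome binning, triplet/bedGraph parsing, and matrix balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microhic.contact_io import (
    ChromSizes,
    ContactMap,
    FormatError,
    balance,
    bin_genome,
    read_bedgraph_gc,
    read_chrom_sizes,
    read_contacts_triplet,
    write_bedgraph,
    write_chrom_sizes,
    write_contacts_triplet,
    GCTrack,
)


class TestChromSizes:
    def test_parses_file_in_order(self, tmp_path):
        p = tmp_path / "chrom.sizes"
        p.write_text("chr1\t100000000\nchrM1\t20000000\n")
        sizes = read_chrom_sizes(p)
        assert sizes.names == ("chr1", "chrM1")
        assert sizes.lengths == (100_000_000, 20_000_000)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("", "no chromosomes"),
            ("chr1\t0\n", "chr1"),
            ("chr1\t100\nchr1\t200\n", "duplicate"),
            ("chr1 100\n", "2 tab-separated"),
            ("chr1\tabc\n", "not an integer"),
        ],
    )
    def test_malformed_input_raises(self, tmp_path, content, match):
        p = tmp_path / "bad.sizes"
        p.write_text(content)
        with pytest.raises(FormatError, match=match):
            read_chrom_sizes(p)

    def test_round_trip(self, tmp_path):
        sizes = ChromSizes(("a", "b"), (123, 456))
        write_chrom_sizes(sizes, tmp_path / "s.tsv")
        assert read_chrom_sizes(tmp_path / "s.tsv") == sizes


class TestBinGenome:
    def test_micro_classification_is_strictly_below_threshold(self):
        sizes = ChromSizes(("a", "b", "c"), (29_999_999, 30_000_000, 100_000_000))
        g = bin_genome(sizes, 1_000_000, micro_threshold_bp=30_000_000)
        assert list(g.chrom_class) == ["micro", "macro", "macro"]

    def test_exact_division(self):
        g = bin_genome(ChromSizes(("a",), (100_000_000,)), 1_000_000, 30_000_000)
        assert g.n_bins == 100
        assert g.bin_start[-1] == 99_000_000
        assert g.bin_end[-1] == 100_000_000

    def test_short_last_bin_kept(self):
        g = bin_genome(ChromSizes(("a",), (1_500_001,)), 1_000_000, 30_000_000)
        assert g.n_bins == 2
        assert (g.bin_start[1], g.bin_end[1]) == (1_000_000, 1_500_001)
        assert g.bin_lengths[1] == 500_001

    def test_global_indices_contiguous_and_total_count(self):
        sizes = ChromSizes(("a", "b", "c"), (2_500_000, 1_000_000, 3_000_001))
        g = bin_genome(sizes, 1_000_000, 30_000_000)
        expected = sum(-(-length // 1_000_000) for length in sizes.lengths)
        assert g.n_bins == expected
        assert np.all(np.diff(g.bin_chrom) >= 0)
        for ci in range(g.n_chroms):
            sl = g.bins_of(ci)
            assert np.all(np.diff(g.bin_start[sl]) > 0)

    def test_bin_index_rejects_off_boundary_start(self):
        g = bin_genome(ChromSizes(("a",), (10_000_000,)), 1_000_000, 30_000_000)
        assert g.bin_index("a", 3_000_000) == 3
        with pytest.raises(ValueError, match="multiple of bin_size"):
            g.bin_index("a", 500_000)


class TestTripletIO:
    def test_symmetric_duplicates_are_summed(self, tmp_path, toy3_genome):
        p = tmp_path / "c.txt"
        p.write_text("0 1 5\n1 0 3\n")
        cmap = read_contacts_triplet(p, toy3_genome)
        assert cmap.n_entries == 1
        assert (cmap.bin1[0], cmap.bin2[0], cmap.counts[0]) == (0, 1, 8.0)

    def test_genomic_dialect_maps_coordinates(self, tmp_path, toy3_genome):
        p = tmp_path / "c.txt"
        p.write_text("chrA 0 50000000 chrB 0 50000000 7\n")
        cmap = read_contacts_triplet(p, toy3_genome)
        assert (cmap.bin1[0], cmap.bin2[0], cmap.counts[0]) == (0, 2, 7.0)

    @pytest.mark.parametrize(
        "line",
        [
            "chrA 25000000 50000000 chrB 0 50000000 7",  # off-boundary start
            "chrZ 0 50000000 chrB 0 50000000 7",  # unknown chromosome
            "0 1 -5",  # negative count
            "0 1",  # wrong column count
        ],
    )
    def test_bad_lines_raise_with_location(self, tmp_path, toy3_genome, line):
        p = tmp_path / "bad.txt"
        p.write_text(line + "\n")
        with pytest.raises(FormatError, match=":1"):
            read_contacts_triplet(p, toy3_genome)

    def test_write_read_round_trip(self, tmp_path, toy3_cmap, toy3_genome):
        p = tmp_path / "rt.txt"
        write_contacts_triplet(toy3_cmap, p)
        back = read_contacts_triplet(p, toy3_genome)
        np.testing.assert_array_equal(back.bin1, toy3_cmap.bin1)
        np.testing.assert_array_equal(back.bin2, toy3_cmap.bin2)
        np.testing.assert_array_equal(back.counts, toy3_cmap.counts)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        entries=st.lists(
            st.tuples(
                st.integers(0, 4), st.integers(0, 4), st.integers(0, 10_000)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_round_trip_lossless_for_integer_counts(self, tmp_path_factory, entries):
        genome = bin_genome(
            ChromSizes(("a", "b"), (150_000_000, 100_000_000)), 50_000_000, 60_000_000
        )
        i, j, v = zip(*entries)
        cmap = ContactMap.from_entries(genome, i, j, [float(x) for x in v])
        p = tmp_path_factory.mktemp("rt") / "c.txt"
        write_contacts_triplet(cmap, p)
        back = read_contacts_triplet(p, genome)
        np.testing.assert_array_equal(back.bin1, cmap.bin1)
        np.testing.assert_array_equal(back.bin2, cmap.bin2)
        np.testing.assert_array_equal(back.counts, cmap.counts)

    def test_symmetry_of_dense_matrix(self, toy3_cmap):
        dense = toy3_cmap.to_dense()
        np.testing.assert_array_equal(dense, dense.T)


class TestBedGraph:
    def test_gc_parses_to_bins(self, tmp_path, toy3_genome):
        p = tmp_path / "gc.bedgraph"
        p.write_text("chrA\t0\t50000000\t0.43\n")
        track = read_bedgraph_gc(p, toy3_genome)
        assert track.gc[0] == 0.43
        assert np.isnan(track.gc[1])

    def test_out_of_range_fraction_rejected(self, tmp_path, toy3_genome):
        p = tmp_path / "gc.bedgraph"
        p.write_text("chrA\t0\t50000000\t1.2\n")
        with pytest.raises(FormatError, match=r"outside \[0, 1\]"):
            read_bedgraph_gc(p, toy3_genome)

    def test_misaligned_interval_rejected_with_offender(self, tmp_path, toy3_genome):
        p = tmp_path / "gc.bedgraph"
        p.write_text("chrA\t1000\t50001000\t0.4\n")
        with pytest.raises(FormatError, match="line 1"):
            read_bedgraph_gc(p, toy3_genome)

    def test_write_read_round_trip(self, tmp_path, toy3_genome):
        gc = np.array([0.4, 0.5, np.nan, 0.61, 0.33])
        track = GCTrack(toy3_genome, gc)
        write_bedgraph(track, tmp_path / "gc.bedgraph")
        back = read_bedgraph_gc(tmp_path / "gc.bedgraph", toy3_genome)
        np.testing.assert_allclose(back.gc, gc)


class TestBalance:
    def test_already_balanced_matrix_untouched(self, toy3_genome):
        # matrix [[0,2],[2,0]] on the first two bins; remaining bins masked
        cmap = ContactMap.from_entries(toy3_genome, [0], [1], [2.0])
        out = balance(cmap, mask_quantile=0.0)
        w = out.balancing_weights
        assert out.balance_converged
        assert w[0] == pytest.approx(w[1])
        dense = out.to_dense(balanced=True)
        assert dense[0].sum() == pytest.approx(dense[1].sum())

    def test_row_sums_converge_on_random_positive_matrix(self, toy3_genome):
        rng = np.random.default_rng(42)
        n = 50
        genome = bin_genome(ChromSizes(("a",), (n,)), 1, 2)
        m = rng.uniform(0.5, 5.0, size=(n, n))
        m = (m + m.T) / 2
        iu = np.triu_indices(n)
        cmap = ContactMap.from_entries(genome, iu[0], iu[1], m[iu])
        out = balance(cmap, tol=1e-7, mask_quantile=0.0)
        assert out.balance_converged
        sums = out.to_dense(balanced=True).sum(axis=1)
        assert np.abs(sums / sums.mean() - 1).max() < 1e-5

    def test_weights_invert_applied_row_scaling(self, toy3_genome):
        rng = np.random.default_rng(7)
        n = 20
        genome = bin_genome(ChromSizes(("a",), (n,)), 1, 2)
        m = rng.uniform(1.0, 3.0, size=(n, n))
        m = (m + m.T) / 2
        iu = np.triu_indices(n)
        base = ContactMap.from_entries(genome, iu[0], iu[1], m[iu])
        w0 = balance(base, tol=1e-10, mask_quantile=0.0).balancing_weights

        c = 4.0
        d = np.ones(n)
        d[3] = c
        scaled = m * np.outer(d, d)  # symmetric scaling D M D of bin 3
        cmap2 = ContactMap.from_entries(genome, iu[0], iu[1], scaled[iu])
        w1 = balance(cmap2, tol=1e-10, mask_quantile=0.0).balancing_weights
        # up to a global factor, weight of the scaled bin shrinks by 1/c
        other = np.arange(n) != 3
        global_factor = np.median(w1[other] / w0[other])
        assert w1[3] / w0[3] / global_factor == pytest.approx(1.0 / c, rel=1e-4)

    def test_all_zero_bin_is_masked_with_zero_weight(self):
        genome = bin_genome(ChromSizes(("a",), (3,)), 1, 2)
        cmap = ContactMap.from_entries(genome, [0], [1], [5.0])  # bin 2 empty
        out = balance(cmap, mask_quantile=0.0)
        assert not out.bin_mask[2]
        assert out.balancing_weights[2] == 0.0
        assert out.balance_converged

    def test_non_convergence_flagged_not_raised(self, toy3_cmap):
        out = balance(toy3_cmap, max_iter=1, tol=1e-16, mask_quantile=0.0)
        assert out.balance_converged is False

    def test_balanced_values_symmetric(self, toy3_cmap):
        out = balance(toy3_cmap, mask_quantile=0.0)
        dense = out.to_dense(balanced=True)
        np.testing.assert_allclose(dense, dense.T)
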