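"""Chromosome-level trans statistics against a brute-force triplet oracle."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy import stats

from microhic import trans_interaction as ti
from microhic.contact_io import ChromSizes, ContactMap, bin_genome


def brute_force_trans(cmap):
    """Independent recomputation of per-chromosome and pairwise trans sums
    by looping over the raw triplet list."""
    g = cmap.genome
    pair = {}
    per_chrom = dict.fromkeys(range(g.n_chroms), 0.0)
    for i, j, v in zip(cmap.bin1, cmap.bin2, cmap.counts):
        ci, cj = int(g.bin_chrom[i]), int(g.bin_chrom[j])
        if ci == cj:
            continue
        key = (min(ci, cj), max(ci, cj))
        pair[key] = pair.get(key, 0.0) + float(v)
        per_chrom[ci] += float(v)
        per_chrom[cj] += float(v)
    return per_chrom, pair


class TestOracleEquivalence:
    """The 3-chromosome toy (L = 100, 100, 50 Mb; O = 100, 150, 150)."""

    def test_icf_densities_match_hand_sums(self, toy3_cmap):
        dens = ti.icf_density(toy3_cmap)
        np.testing.assert_allclose(dens.to_numpy(), [2.5, 2.5, 6.0], atol=1e-9)

    def test_expected_icf_length_product_null(self, toy3_cmap):
        exp = ti.expected_icf(toy3_cmap)
        # pair products 1e4, 5e3, 5e3 (sum 2e4); T = 400 -> E = 200, 100, 100
        np.testing.assert_allclose(
            [exp[0, 1], exp[0, 2], exp[1, 2]], [200.0, 100.0, 100.0], atol=1e-9
        )

    def test_log2_ratios_match_hand_arithmetic(self, toy3_cmap):
        obs = ti.chrom_pair_observed(toy3_cmap)
        log2r = ti.oe_log2(obs, ti.expected_icf(toy3_cmap))
        np.testing.assert_allclose(
            [log2r[0, 1], log2r[0, 2], log2r[1, 2]],
            [-1.0, np.log2(1.5), np.log2(1.5)],
            atol=1e-9,
        )

    def test_micro_involvement_hand_sum(self, toy3_cmap):
        invol = ti.micro_involvement(toy3_cmap)
        # A: 150 of 250 trans contacts go to micro chrC
        assert invol["chrA"] == pytest.approx(0.6, abs=1e-9)
        assert invol["chrC"] == pytest.approx(0.0, abs=1e-9)  # no other micro

    def test_matches_brute_force_recomputation(self, toy3_cmap):
        per_chrom, pair = brute_force_trans(toy3_cmap)
        g = toy3_cmap.genome
        obs = ti.chrom_pair_observed(toy3_cmap)
        for (ci, cj), v in pair.items():
            assert obs[ci, cj] == pytest.approx(v, abs=1e-9)
        dens = ti.icf_density(toy3_cmap)
        for ci in range(g.n_chroms):
            expected = per_chrom[ci] / (g.chrom_lengths[ci] / 1e6)
            assert dens.iloc[ci] == pytest.approx(expected, abs=1e-9)


class TestExpectedNull:
    def test_conservation_sum_expected_equals_sum_observed(self, toy3_cmap, balanced_default):
        for cmap in (toy3_cmap, balanced_default):
            obs = ti.chrom_pair_observed(cmap)
            exp = ti.expected_icf(cmap)
            iu = np.triu_indices(cmap.genome.n_chroms, k=1)
            assert exp[iu].sum() == pytest.approx(obs[iu].sum(), rel=1e-12)

    def test_two_equal_chromosomes_single_pair(self):
        g = bin_genome(ChromSizes(("a", "b"), (10**7, 10**7)), 10**7, 10**6)
        cmap = ContactMap.from_entries(g, [0], [1], [42.0])
        exp = ti.expected_icf(cmap)
        assert exp[0, 1] == pytest.approx(42.0)

    def test_equal_lengths_give_uniform_expected(self):
        g = bin_genome(ChromSizes(("a", "b", "c", "d"), (10**7,) * 4), 10**7, 10**6)
        cmap = ContactMap.from_entries(g, [0, 0, 0, 1, 1, 2], [1, 2, 3, 2, 3, 3], [10.0] * 6)
        exp = ti.expected_icf(cmap)
        iu = np.triu_indices(4, k=1)
        np.testing.assert_allclose(exp[iu], 10.0)

    def test_marginal_null_uses_trans_sums(self, toy3_cmap):
        exp = ti.expected_icf(toy3_cmap, null="marginal")
        obs = ti.chrom_pair_observed(toy3_cmap)
        s = obs.sum(axis=1)  # 250, 250, 300
        prod = np.outer(s, s)
        iu = np.triu_indices(3, k=1)
        np.testing.assert_allclose(exp[iu], 400.0 * prod[iu] / prod[iu].sum())

    def test_no_trans_contacts_errors(self):
        g = bin_genome(ChromSizes(("a", "b"), (2 * 10**7, 10**7)), 10**7, 10**6)
        cmap = ContactMap.from_entries(g, [0], [1], [5.0])  # cis only
        with pytest.raises(ValueError, match="no trans"):
            ti.expected_icf(cmap)

    def test_single_chromosome_errors(self):
        g = bin_genome(ChromSizes(("a",), (2 * 10**7,)), 10**7, 10**6)
        cmap = ContactMap.from_entries(g, [0], [1], [5.0])
        with pytest.raises(ValueError, match="single chromosome"):
            ti.icf_density(cmap)


class TestScaleInvariance:
    def test_log2_oe_invariant_to_count_rescaling(self, toy3_cmap):
        scaled = ContactMap.from_entries(
            toy3_cmap.genome, toy3_cmap.bin1, toy3_cmap.bin2, toy3_cmap.counts * 37.0
        )
        base = ti.oe_log2(ti.chrom_pair_observed(toy3_cmap), ti.expected_icf(toy3_cmap))
        after = ti.oe_log2(ti.chrom_pair_observed(scaled), ti.expected_icf(scaled))
        iu = np.triu_indices(3, k=1)
        np.testing.assert_allclose(after[iu], base[iu], atol=1e-12)

    def test_densities_scale_linearly(self, toy3_cmap):
        scaled = ContactMap.from_entries(
            toy3_cmap.genome, toy3_cmap.bin1, toy3_cmap.bin2, toy3_cmap.counts * 3.0
        )
        np.testing.assert_allclose(
            ti.icf_density(scaled).to_numpy(), 3.0 * ti.icf_density(toy3_cmap).to_numpy()
        )


class TestOELog2:
    def test_zero_where_observed_equals_expected(self):
        m = np.array([[0.0, 5.0], [5.0, 0.0]])
        out = ti.oe_log2(m, m)
        assert out[0, 1] == 0.0
        assert np.isnan(out[0, 0])

    def test_pseudocount_keeps_zero_observed_finite(self):
        obs = np.array([[0.0, 0.0], [0.0, 0.0]])
        exp = np.array([[0.0, 8.0], [8.0, 0.0]])
        out = ti.oe_log2(obs, exp, pseudocount=1.0)
        assert np.isfinite(out[0, 1]) and out[0, 1] < 0


class TestClustering:
    def test_identical_rows_merge_first_at_zero_height(self):
        # rows 0 and 1 are identical after the diagonal is imputed to 0
        m = np.array(
            [
                [np.nan, 0.0, 2.0, 3.0],
                [0.0, np.nan, 2.0, 3.0],
                [2.0, 2.0, np.nan, -1.0],
                [3.0, 3.0, -1.0, np.nan],
            ]
        )
        linkage, _ = ti.cluster_chromosomes(m)
        assert linkage[0, 0] == 0 and linkage[0, 1] == 1
        assert linkage[0, 2] == pytest.approx(0.0)

    def test_two_chromosomes_single_merge(self):
        m = np.array([[np.nan, 0.3], [0.3, np.nan]])
        linkage, leaves = ti.cluster_chromosomes(m)
        assert linkage.shape == (1, 4)
        assert sorted(leaves) == [0, 1]

    def test_two_cut_separates_planted_classes(self, balanced_default, default_dataset):
        ts = ti.trans_summary(balanced_default)
        groups = sch.fcluster(ts.linkage, 2, criterion="maxclust")
        is_micro = default_dataset.genome.is_micro
        assert len(set(groups[is_micro])) == 1
        assert len(set(groups[~is_micro])) == 1
        assert set(groups[is_micro]) != set(groups[~is_micro])

    def test_newick_round_trips_all_leaves(self, toy3_cmap):
        ts = ti.trans_summary(toy3_cmap, balanced=False)
        nwk = ts.newick()
        for name in toy3_cmap.genome.chrom_names:
            assert name in nwk
        assert nwk.endswith(";")


class TestGroupComparison:
    def test_identical_groups_give_zero_t(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        classes = np.array(["micro"] * 3 + ["macro"] * 3)
        res = ti.compare_groups(values, classes)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_shifted_group_matches_closed_form_t(self):
        # (1,2,3) vs (11,12,13): pooled t = -10 / sqrt(1 * 2/3)
        values = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        classes = np.array(["micro"] * 3 + ["macro"] * 3)
        res = ti.compare_groups(values, classes)
        expected_t = -10.0 / np.sqrt(1.0 * (2.0 / 3.0))
        assert res.statistic == pytest.approx(expected_t)
        assert res.pvalue < 0.001

    def test_welch_variant_matches_scipy(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=10)
        classes = np.array(["micro"] * 4 + ["macro"] * 6)
        res = ti.compare_groups(values, classes, test="welch")
        ref = stats.ttest_ind(values[:4], values[4:], equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_small_class_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            ti.compare_groups(np.array([1.0, 2.0]), np.array(["micro", "macro"]))


class TestRegression:
    def test_perfect_line_recovered(self):
        lengths = np.array([10e6, 20e6, 30e6, 40e6])
        dens = 2.0 * (lengths / 1e6) + 1.0
        res = ti.regress_density_on_length(dens, lengths)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        lengths = np.array([10e6, 20e6, 30e6, 40e6])
        res = ti.regress_density_on_length(np.full(4, 3.3), lengths)
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_synthetic_dataset_density_falls_with_length(self, balanced_default):
        ts = ti.trans_summary(balanced_default)
        assert ts.regression.slope < 0
        assert ts.regression_log10.slope < 0


class TestRecovery:
    def test_micro_density_exceeds_macro_on_synthetic(self, balanced_default):
        ts = ti.trans_summary(balanced_default)
        assert ts.density_test.mean_micro > ts.density_test.mean_macro
        assert ts.density_test.pvalue < 0.01

    def test_microchromosome_pair_enrichment_signs(self, balanced_default, default_dataset):
        ts = ti.trans_summary(balanced_default)
        is_micro = default_dataset.genome.is_micro
        n = len(is_micro)
        mm, xm = [], []
        for k in range(n):
            for l in range(k + 1, n):
                if is_micro[k] and is_micro[l]:
                    mm.append(ts.log2_ratio[k, l])
                elif is_micro[k] != is_micro[l]:
                    xm.append(ts.log2_ratio[k, l])
        assert np.mean(mm) > 0
        assert np.mean(xm) < 0
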