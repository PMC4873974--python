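"""Promoter windows, site counting, permutation null and ORA oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comboscreen import (RegulatoryTruth, TFBSPermutationTest, count_sites,
                         gen_gene_annotation, gen_regulatory, hypergeom_ora,
                         promoter_windows, tfbs_permutation_test)
from comboscreen.enrichment import PromoterWindow, ora_table


def annotation(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


class TestPromoterWindows:
    def test_plus_strand_window(self):
        w = promoter_windows(annotation([("g", "chr1", 100000, "+")]))[0]
        assert (w.start, w.end) == (95000, 101000)

    def test_minus_strand_window_mirrored(self):
        w = promoter_windows(annotation([("g", "chr1", 100000, "-")]))[0]
        assert (w.start, w.end) == (99000, 105000)

    def test_clipped_at_zero(self):
        w = promoter_windows(annotation([("g", "chr1", 1000, "+")]))[0]
        assert (w.start, w.end) == (0, 2000)

    def test_strand_aware_flag_disables_orientation(self):
        w = promoter_windows(annotation([("g", "chr1", 100000, "-")]),
                             strand_aware=False)[0]
        assert (w.start, w.end) == (95000, 101000)


class TestCountSites:
    WINDOWS = [PromoterWindow("g1", "chr1", 95000, 101000)]

    def bed(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf"])

    def test_overlapping_site_counted(self):
        counts = count_sites(self.WINDOWS, self.bed([("chr1", 96000, 96010, "TF1")]))
        assert counts.loc["g1", "TF1"] == 1

    def test_adjacent_half_open_site_not_counted(self):
        counts = count_sites(self.WINDOWS, self.bed([("chr1", 94990, 95000, "TF1")]))
        assert counts.loc["g1", "TF1"] == 0

    def test_one_bp_overlap_counts(self):
        counts = count_sites(self.WINDOWS, self.bed([("chr1", 94991, 95001, "TF1")]))
        assert counts.loc["g1", "TF1"] == 1

    def test_empty_bed_gives_zero_matrix(self):
        counts = count_sites(self.WINDOWS, self.bed([]))
        assert counts.shape == (1, 0)

    def test_site_spanning_two_windows_counts_in_both(self):
        windows = [PromoterWindow("g1", "chr1", 100, 200),
                   PromoterWindow("g2", "chr1", 150, 300)]
        counts = count_sites(windows, self.bed([("chr1", 160, 170, "TF1")]))
        assert counts.loc["g1", "TF1"] == 1 and counts.loc["g2", "TF1"] == 1

    def test_malformed_interval_rejected_with_row(self):
        with pytest.raises(ValueError, match="row 0"):
            count_sites(self.WINDOWS, self.bed([("chr1", 50, 50, "TF1")]))


class TestPermutationTest:
    def exact_tail(self, counts, genes, k, x_obs):
        hits = total = 0
        for subset in itertools.combinations(genes, k):
            total += 1
            hits += counts.loc[list(subset)].sum() >= x_obs
        return hits / total

    def test_constant_statistic_gives_p_one(self):
        counts = pd.DataFrame({"TFa": np.ones(6, dtype=int)},
                              index=[f"g{i}" for i in range(6)])
        res = tfbs_permutation_test(counts, counts.index, ["g0", "g1"],
                                    n_perm=1000, seed=0)
        assert res.table.loc["TFa", "p_emp"] == pytest.approx(1.0, abs=2e-3)

    def test_matches_exhaustive_enumeration(self):
        # p=6 genes, counts {3,0,0,0,0,0}, k=2, DEGs include the 3-count
        # gene: exact tail = #{subsets with sum >= 3}/C(6,2) = 5/15
        counts = pd.DataFrame({"TFa": [3, 0, 0, 0, 0, 0]},
                              index=[f"g{i}" for i in range(6)])
        exact = self.exact_tail(counts["TFa"], counts.index, 2, 3)
        assert exact == pytest.approx(5 / 15)
        n_perm = 100_000
        res = tfbs_permutation_test(counts, counts.index, ["g0", "g1"],
                                    n_perm=n_perm, seed=3)
        mc_sd = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.table.loc["TFa", "p_emp"] - exact) < 3 * mc_sd

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(21)
        for trial in range(3):
            p, k = 8, 3  # C(8,3) = 56 subsets
            counts = pd.DataFrame(
                {"TFa": rng.poisson(1.0, p), "TFb": rng.poisson(2.0, p)},
                index=[f"g{i}" for i in range(p)])
            degs = list(counts.index[:k])
            res = tfbs_permutation_test(counts, counts.index, degs,
                                        n_perm=50_000, seed=trial)
            for tf in ("TFa", "TFb"):
                x_obs = counts.loc[degs, tf].sum()
                exact = self.exact_tail(counts[tf], counts.index, k, x_obs)
                mc_sd = max(np.sqrt(exact * (1 - exact) / 50_000), 1e-4)
                assert abs(res.table.loc[tf, "p_emp"] - exact) < 3 * mc_sd

    def test_determinism_and_tf_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(1.0, (30, 3)),
                              index=[f"g{i}" for i in range(30)],
                              columns=["TF1", "TF2", "TF3"])
        degs = [f"g{i}" for i in range(5)]
        r1 = tfbs_permutation_test(counts, counts.index, degs, 2000, seed=5)
        r2 = tfbs_permutation_test(counts, counts.index, degs, 2000, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        r3 = tfbs_permutation_test(counts[["TF3", "TF1", "TF2"]], counts.index,
                                   degs, 2000, seed=5)
        for tf in ("TF1", "TF2", "TF3"):
            assert r3.table.loc[tf, "p_emp"] == r1.table.loc[tf, "p_emp"]

    def test_monotone_in_observed_statistic(self):
        # raising X_obs with the same null never increases p_emp
        rng = np.random.default_rng(4)
        base = rng.poisson(1.0, 40)
        index = [f"g{i}" for i in range(40)]
        p_at = []
        for bump in (0, 3, 6):
            counts = pd.DataFrame({"TFa": base.copy()}, index=index)
            counts.iloc[0, 0] += bump
            res = tfbs_permutation_test(counts, index, ["g0", "g1", "g2"],
                                        n_perm=5000, seed=9)
            p_at.append(res.table.loc["TFa", "p_emp"])
        assert p_at[0] >= p_at[1] >= p_at[2]

    def test_degs_outside_universe_rejected(self):
        counts = pd.DataFrame({"TFa": [1, 2]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="subset"):
            tfbs_permutation_test(counts, ["g0"], ["g1"], 10, 0)

    def test_k_equals_p_degenerate(self):
        counts = pd.DataFrame({"TFa": [1, 2]}, index=["g0", "g1"])
        res = tfbs_permutation_test(counts, counts.index, ["g0", "g1"], 100, 0)
        assert res.table.loc["TFa", "p_emp"] == pytest.approx(1.0)
        assert res.flags

    def test_null_pvalues_calibrated(self):
        # DEGs drawn at random: p_emp approximately uniform (conservative)
        rng = np.random.default_rng(31)
        p, k = 300, 20
        index = [f"g{i}" for i in range(p)]
        pvals = []
        for seed in range(200):
            counts = pd.DataFrame(
                {"TFa": np.random.default_rng(1000 + seed).poisson(0.5, p)},
                index=index)
            degs = list(rng.choice(index, size=k, replace=False))
            res = tfbs_permutation_test(counts, index, degs, n_perm=999,
                                        seed=seed)
            pvals.append(res.table.loc["TFa", "p_emp"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        # conservative in the rejection region
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / 200)

    def test_planted_enrichment_detected(self):
        # 5x promoter-site rate for one TF over 50 DEGs of 2000 genes
        genes = [f"G{i}" for i in range(2000)]
        ann = gen_gene_annotation(genes, seed=5)
        degs = genes[:50]
        truth = RegulatoryTruth(tfs=("TF1", "TF2", "TF3"),
                                enriched_tfs=("TF1",), rate_background=0.5,
                                rate_enriched=2.5)
        bed = gen_regulatory(truth, ann, degs, seed=11)
        counts = count_sites(promoter_windows(ann), bed)
        res = tfbs_permutation_test(counts, genes, degs, n_perm=100_000,
                                    seed=7)
        assert res.table.loc["TF1", "p_emp"] < 0.01
        assert (res.table.drop("TF1")["p_emp"] > 0.05).all()


class TestORA:
    def test_matches_binomial_coefficient_arithmetic(self):
        # universe 10, set 5, degs 4, overlap 4: C(5,4) C(5,0) / C(10,4)
        universe = [f"g{i}" for i in range(10)]
        gene_set = universe[:5]
        degs = universe[:4]
        overlap, p, score = hypergeom_ora(degs, gene_set, universe)
        assert overlap == 4
        assert p == pytest.approx(5 / 210)
        assert score == pytest.approx(-np.log10(5 / 210))

    def test_gene_set_equal_to_universe_forces_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        _, p, _ = hypergeom_ora(universe[:3], universe, universe)
        assert p == pytest.approx(1.0)

    def test_disjoint_sets_give_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        _, p, _ = hypergeom_ora(universe[:3], universe[5:], universe)
        assert p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_ora(["a"], ["a"], [])

    def test_ora_table_ranks_by_score(self):
        universe = [f"g{i}" for i in range(100)]
        degs = universe[:10]
        sets = {"hit": universe[:10], "half": universe[5:15],
                "miss": universe[50:60]}
        table = ora_table(degs, sets, universe, top=10)
        assert list(table["gene_set"]) == ["hit", "half", "miss"]
        assert table["score"].is_monotonic_decreasing
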