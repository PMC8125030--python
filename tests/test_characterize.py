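"""GC, coverage matrices, and nonparametric group comparisons."""

import numpy as np
import pytest
from scipy import stats

from retime import (
    Interval,
    RegionSet,
    compare_region_groups,
    large_gene_coverage,
    mark_coverage_matrix,
    region_gc,
    region_stats_table,
)
from retime.characterize import linkage_to_newick


class TestRegionGC:
    def test_simple_sequences(self):
        fasta = {"1": "ACGTAAAA"}
        rs = RegionSet([Interval("1", 0, 4), Interval("1", 4, 8)])
        np.testing.assert_allclose(region_gc(rs, fasta), [0.5, 0.0])

    def test_ambiguous_bases_leave_denominator(self):
        fasta = {"1": "GGNNNNAA"}
        rs = RegionSet([Interval("1", 0, 8)])
        assert region_gc(rs, fasta)[0] == pytest.approx(0.5)

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            region_gc(RegionSet([Interval("1", 0, 100)]), {"1": "ACGT"})

    def test_missing_chromosome_rejected(self):
        with pytest.raises(ValueError, match="no sequence"):
            region_gc(RegionSet([Interval("2", 0, 2)]), {"1": "ACGT"})

    def test_matches_base_count_oracle_on_synthetic_genome(self, small_genome):
        seqs = small_genome["seqs"]
        rng = np.random.default_rng(0)
        ivs = []
        for _ in range(30):
            c = "1" if rng.random() < 0.5 else "2"
            s = int(rng.integers(0, 490_000))
            ivs.append(Interval(c, s, s + int(rng.integers(1_000, 10_000))))
        rs = RegionSet(ivs)
        got = region_gc(rs, seqs)
        for k, iv in enumerate(rs):
            seq = seqs[iv.chrom][iv.start : iv.end]
            counts = {b: seq.count(b) for b in "ACGTN"}
            denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
            assert got[k] == pytest.approx((counts["G"] + counts["C"]) / denom)

    def test_region_stats_table_columns(self, small_genome):
        rs = RegionSet([Interval("1", 0, 10_000), Interval("2", 0, 20_000)])
        feats = {"origins": RegionSet([Interval("1", 0, 5_000)])}
        df = region_stats_table(rs, small_genome["seqs"], feats)
        assert list(df.columns) == ["chrom", "start", "end", "size", "gc", "cov_origins"]
        assert df["size"].tolist() == [10_000, 20_000]
        assert df["cov_origins"].tolist() == [0.5, 0.0]


class TestLargeGeneCoverage:
    def test_strict_length_threshold(self):
        regions = RegionSet([Interval("1", 0, 1_000_000)])
        kept = RegionSet([Interval("1", 0, 450_000, name="big")])
        excluded = RegionSet([Interval("1", 0, 400_000, name="edge")])
        assert large_gene_coverage(regions, kept)[0] == pytest.approx(0.45)
        assert large_gene_coverage(regions, excluded)[0] == 0.0

    def test_no_large_genes_gives_zeros(self):
        regions = RegionSet([Interval("1", 0, 1_000_000)])
        genes = RegionSet([Interval("1", i * 1_000, i * 1_000 + 500) for i in range(10)])
        np.testing.assert_array_equal(large_gene_coverage(regions, genes), [0.0])

    def test_matches_filtered_oracle(self):
        rng = np.random.default_rng(1)
        regions = RegionSet([Interval("1", int(s), int(s) + 500_000) for s in rng.integers(0, 9_500_000, 5)])
        genes = RegionSet(
            [Interval("1", int(s), int(s) + int(L)) for s, L in
             zip(rng.integers(0, 9_000_000, 40), rng.integers(100_000, 900_000, 40))]
        )
        from retime import coverage_fraction

        big = RegionSet([g for g in genes if g.length > 400_000])
        np.testing.assert_allclose(
            large_gene_coverage(regions, genes), coverage_fraction(regions, big)
        )


class TestCoverageMatrix:
    def groups_and_marks(self):
        g1 = RegionSet([Interval("1", 0, 1_000), Interval("1", 5_000, 6_000)], "g1")
        g2 = RegionSet([Interval("1", 10_000, 11_000)], "g2")
        g3 = RegionSet([Interval("1", 20_000, 21_000)], "g3")
        m_match = RegionSet([Interval("1", 0, 1_000), Interval("1", 5_000, 6_000)], "m1")
        m_other = RegionSet([Interval("1", 10_500, 11_000)], "m2")
        return {"g1": g1, "g2": g2, "g3": g3}, {"m1": m_match, "m2": m_other}

    def test_matching_mark_is_column_max(self):
        groups, marks = self.groups_and_marks()
        cm = mark_coverage_matrix(groups, marks)
        assert cm.matrix.loc["g1", "m1"] == 1.0
        assert cm.raw.loc["g1", "m1"] == 1.0

    def test_identical_groups_give_identical_rows(self):
        groups, marks = self.groups_and_marks()
        groups["g1b"] = RegionSet(list(groups["g1"]), "g1b")
        cm = mark_coverage_matrix(groups, marks)
        np.testing.assert_allclose(cm.matrix.loc["g1"], cm.matrix.loc["g1b"])

    def test_constant_column_normalizes_to_zero(self):
        groups, _ = self.groups_and_marks()
        everywhere = RegionSet([Interval("1", 0, 30_000)], "all")
        cm = mark_coverage_matrix(groups, {"const": everywhere, "m2": self.groups_and_marks()[1]["m2"]})
        assert (cm.matrix["const"] == 0.0).all()

    def test_cell_values_invariant_to_region_order(self):
        groups, marks = self.groups_and_marks()
        reordered = {k: RegionSet(list(v)[::-1], v.label) for k, v in groups.items()}
        a = mark_coverage_matrix(groups, marks).raw
        b = mark_coverage_matrix(reordered, marks).raw
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_normalization_idempotent(self):
        groups, marks = self.groups_and_marks()
        cm = mark_coverage_matrix(groups, marks)
        renorm = cm.matrix.copy()
        for col in renorm.columns:
            lo, hi = renorm[col].min(), renorm[col].max()
            renorm[col] = 0.0 if hi <= lo else (renorm[col] - lo) / (hi - lo)
        np.testing.assert_allclose(renorm.to_numpy(), cm.matrix.to_numpy())

    def test_adv_clusters_with_late_on_synthetic_marks(self, default_cohort, default_tracks):
        """Advanced regions keep the chromatin signature of the late
        domains they came from, so their mark profile clusters with Late."""
        truth = default_cohort["truth"]
        artil = default_cohort["artil"]
        groups = {
            "Early": truth.early,
            "Late": truth.late,
            "ADV": artil.to_region_set("ADV"),
        }
        cm = mark_coverage_matrix(groups, default_tracks["marks"])
        corr = np.corrcoef(cm.matrix.to_numpy())
        idx = {g: i for i, g in enumerate(cm.matrix.index)}
        assert corr[idx["ADV"], idx["Late"]] > corr[idx["ADV"], idx["Early"]]

    def test_newick_renders_all_labels(self):
        groups, marks = self.groups_and_marks()
        cm = mark_coverage_matrix(groups, marks)
        nwk = linkage_to_newick(cm.row_linkage, list(cm.matrix.index))
        assert nwk.endswith(";")
        for g in groups:
            assert g in nwk


class TestGroupComparison:
    def test_all_tied_gives_p_one(self):
        res = compare_region_groups({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0]})
        assert res.omnibus_p == 1.0

    def test_extreme_separation_gives_minimal_p(self):
        res = compare_region_groups({"a": [1, 2, 3], "b": [101, 102, 103]})
        # smallest achievable Kruskal-Wallis p for 3+3 without ties
        h_max = stats.kruskal([1, 2, 3], [4, 5, 6])[0]
        assert res.omnibus_statistic == pytest.approx(h_max)
        assert res.omnibus_p == pytest.approx(stats.chi2.sf(h_max, 1))

    def test_two_group_dunn_z_squares_to_kruskal_h(self):
        """With exactly two groups Dunn's z statistic satisfies z^2 == H."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.standard_normal(8), rng.standard_normal(5) + 0.5
            res = compare_region_groups({"a": a, "b": b})
            z = res.pairwise["z"].iloc[0]
            assert z**2 == pytest.approx(res.omnibus_statistic)

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.standard_normal(6) + d for g, d in (("a", 0), ("b", 1), ("c", 3))}
        res = compare_region_groups(groups)
        assert (res.pairwise["p_adjusted"] >= res.pairwise["p_raw"] - 1e-12).all()
        bonf = compare_region_groups(groups, adjust="bonferroni")
        assert (bonf.pairwise["p_adjusted"] >= res.pairwise["p_adjusted"] - 1e-12).all()

    def test_type_one_error_calibrated(self):
        """Omnibus rejects ~5% of null datasets at alpha = 0.05."""
        rng = np.random.default_rng(4)
        rej = 0
        n_sim = 800
        for _ in range(n_sim):
            groups = {g: rng.standard_normal(8) for g in ("a", "b", "c")}
            rej += compare_region_groups(groups).omnibus_p < 0.05
        assert 0.03 < rej / n_sim < 0.075

    def test_requires_two_values_per_group(self):
        with pytest.raises(ValueError, match=">=2"):
            compare_region_groups({"a": [1.0], "b": [1.0, 2.0]})
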