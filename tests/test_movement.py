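"""Movement classification, the size-based null, and the 2×3 exact test."""
import numpy as np
import pytest

from synmito import classify_movements, expected_movements, fisher_exact_2x3
from synmito.movement import CATEGORIES, movement_table
from synmito.orthology import OrthologMap
from synmito.synteny import MergedRegion, SyntenyBlock

from conftest import make_anchors, make_catalog


# frozen independent oracle values: R 4.3.3 fisher.test on the same tables
R_FISHER_2X3 = [
    (((0, 4, 132), (2, 4, 130)), 0.6395122),
    (((3, 3, 92), (4, 4, 90)), 0.8448342),
    (((7, 2, 11), (3, 9, 5)), 0.02170826),
    (((1, 0, 0), (0, 1, 1)), 1.0),
    (((12, 5, 0), (2, 8, 7)), 0.0003851901),
]


class TestFisher2x3:
    @pytest.mark.parametrize("table,expected_p", R_FISHER_2X3)
    def test_matches_r_fisher_test(self, table, expected_p):
        obs, exp = table
        assert fisher_exact_2x3(obs, exp) == pytest.approx(expected_p, rel=1e-5)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x3((5, 7, 11), (5, 7, 11)) == 1.0

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            obs = rng.integers(0, 30, 3)
            exp = rng.integers(0, 30, 3)
            if obs.sum() == 0 and exp.sum() == 0:
                continue
            p = fisher_exact_2x3(list(obs), list(exp))
            assert 0.0 <= p <= 1.0

    def test_non_integer_expected_rejected_with_rounding_hint(self):
        with pytest.raises(ValueError, match="round"):
            fisher_exact_2x3((1, 2, 3), (1.5, 2, 2.5))

    def test_degenerate_zero_column_matches_2x2_hypergeometric(self):
        # with one empty column the 2x3 test collapses to a 2x2 test
        from scipy.stats import fisher_exact as f22
        obs, exp = (6, 0, 14), (2, 0, 18)
        p23 = fisher_exact_2x3(obs, exp)
        p22 = f22([[6, 14], [2, 18]])[1]
        assert p23 == pytest.approx(p22, rel=1e-10)


class TestExpectedMovements:
    def _setup(self, n_focal_b=5, n_other_b=95):
        # genome A: focal chromosome is 5% of assembly bp
        cat_a = make_catalog("A", {"chrX": [("ax", 0, 100)],
                                   "chr2": [("a2", 0, 100)]},
                             chrom_len=1_000_000)
        cat_a.chrom_lengths["chrX"] = 100_000
        cat_a.chrom_lengths["chr2"] = 1_900_000
        genes_b = {"chr6": [(f"bf{i}", i * 1000, i * 1000 + 500) for i in range(n_focal_b)],
                   "chr7": [(f"bo{i}", i * 1000, i * 1000 + 500) for i in range(n_other_b)]}
        cat_b = make_catalog("B", genes_b, chrom_len=1_000_000)
        omap = OrthologMap(pairs=[(f"x{i}", g[0]) for i, g in
                                  enumerate(genes_b["chr6"] + genes_b["chr7"])])
        focal_region = MergedRegion("chrX", "chr6", (0, 100_000), (0, 200_000), [])
        return cat_a, cat_b, omap, focal_region

    def test_degenerate_all_mass_on_autosome_autosome(self):
        cat_a, cat_b, omap, _ = self._setup(n_focal_b=0, n_other_b=100)
        cat_a.chrom_lengths["chrX"] = 0
        expected, e_xx = expected_movements(cat_a, cat_b, omap, 10, "chrX", [])
        assert expected["A>A"] == pytest.approx(10.0)
        assert expected["X>A"] == expected["A>X"] == 0.0 and e_xx == 0.0

    def test_hand_arithmetic_with_five_percent_compartments(self):
        cat_a, cat_b, omap, region = self._setup()
        expected, e_xx = expected_movements(
            cat_a, cat_b, omap, 100, "chrX", [region])
        # P(src)=P(tgt)=0.05: T*p*(1-q)/(1-pq) etc.
        assert expected["X>A"] == pytest.approx(4.7619, abs=1e-3)
        assert expected["A>X"] == pytest.approx(4.7619, abs=1e-3)
        assert expected["A>A"] == pytest.approx(90.476, abs=1e-2)
        assert sum(expected.values()) == pytest.approx(100.0)
        assert e_xx == pytest.approx(0.25, abs=1e-6)

    def test_zero_observed_total_all_zero(self):
        cat_a, cat_b, omap, region = self._setup()
        expected, e_xx = expected_movements(cat_a, cat_b, omap, 0, "chrX", [region])
        assert all(v == 0.0 for v in expected.values()) and e_xx == 0.0


def _movement_scene():
    """Two genomes, one X<->6 region, plus genes placed in/out of synteny."""
    cat_a = make_catalog("A", {
        "chrX": [("aX1", 0, 1000), ("aX2", 10_000, 11_000),
                 ("aMoved", 500_000, 501_000)],
        "chr2": [("a21", 0, 1000), ("aOff", 600_000, 601_000)],
    }, chrom_len=1_000_000)
    cat_b = make_catalog("B", {
        "chr6": [("b61", 0, 1000), ("b62", 10_000, 11_000)],
        "contig9": [("bC1", 0, 1000), ("bC2", 5_000, 6_000)],
    }, chrom_len=1_000_000)
    anchors = [a for a in make_anchors([(0, 0), (1, 1)], chrom_a="chrX", chrom_b="chr6")]
    block = SyntenyBlock("chrX", "chr6",
                         [type(a)(pair=p, chrom_a="chrX", chrom_b="chr6",
                                  rank_a=i, rank_b=i,
                                  span_a=(i * 10_000, i * 10_000 + 1000),
                                  span_b=(i * 10_000, i * 10_000 + 1000))
                          for i, (p, a) in enumerate(
                              zip([("aX1", "b61"), ("aX2", "b62")], anchors))],
                         "same")
    region = MergedRegion("chrX", "chr6", (0, 20_000), (0, 20_000), [block])
    return cat_a, cat_b, region


class TestClassifyMovements:
    def test_anchored_pair_is_retained(self):
        cat_a, cat_b, region = _movement_scene()
        cat_a = cat_a.with_mtn_flags({"aX1", "aX2"})
        omap = OrthologMap(pairs=[("aX1", "b61"), ("aX2", "b62")])
        obs = classify_movements(omap, [region], cat_a, cat_b, "chrX")
        assert obs.n_retained == 2 and obs.total == 0

    def test_ortholog_on_non_syntenic_contig_counts_onto_focal(self):
        # gene on the focal chromosome whose ortholog sits on a non-syntenic
        # contig: a candidate movement onto the focal chromosome
        cat_a, cat_b, region = _movement_scene()
        cat_a = cat_a.with_mtn_flags({"aMoved"})
        omap = OrthologMap(pairs=[("aMoved", "bC1")])
        obs = classify_movements(omap, [region], cat_a, cat_b, "chrX")
        assert obs.observed == {"X>A": 0, "A>X": 1, "A>A": 0}

    def test_autosome_to_autosome(self):
        cat_a, cat_b, region = _movement_scene()
        cat_a = cat_a.with_mtn_flags({"aOff"})
        omap = OrthologMap(pairs=[("aOff", "bC2")])
        obs = classify_movements(omap, [region], cat_a, cat_b, "chrX")
        assert obs.observed == {"X>A": 0, "A>X": 0, "A>A": 1}

    def test_origin_inside_focal_region_counts_off_focal(self):
        cat_a, cat_b, region = _movement_scene()
        cat_b_extra = make_catalog("B", {
            "chr6": [("b61", 0, 1000), ("b62", 10_000, 11_000),
                     ("bIn", 15_000, 16_000)],
            "contig9": [("bC1", 0, 1000), ("bC2", 5_000, 6_000)],
        }, chrom_len=1_000_000)
        cat_a = cat_a.with_mtn_flags({"aOff"})
        omap = OrthologMap(pairs=[("aOff", "bIn")])
        obs = classify_movements(omap, [region], cat_a, cat_b_extra, "chrX")
        assert obs.observed == {"X>A": 1, "A>X": 0, "A>A": 0}

    def test_partially_syntenic_source_flagged_ambiguous(self):
        # ortholog on chr6 but outside the syntenic interval: counted as an
        # autosomal source in the primary tally, excluded in the sensitivity one
        cat_a, cat_b, region = _movement_scene()
        cat_b_far = make_catalog("B", {
            "chr6": [("b61", 0, 1000), ("b62", 10_000, 11_000),
                     ("bFar", 900_000, 901_000)],
            "contig9": [("bC1", 0, 1000), ("bC2", 5_000, 6_000)],
        }, chrom_len=1_000_000)
        cat_a = cat_a.with_mtn_flags({"aMoved"})
        omap = OrthologMap(pairs=[("aMoved", "bFar")])
        obs = classify_movements(omap, [region], cat_a, cat_b_far, "chrX")
        assert obs.observed["A>X"] == 1
        assert obs.records[0].ambiguous_origin
        assert obs.without_ambiguous()["A>X"] == 0

    def test_non_mtn_pairs_ignored_under_class_filter(self):
        cat_a, cat_b, region = _movement_scene()
        omap = OrthologMap(pairs=[("aOff", "bC2")])  # aOff not flagged mt-N
        obs = classify_movements(omap, [region], cat_a, cat_b, "chrX")
        assert obs.total == 0 and obs.n_retained == 0


def test_zero_movement_genome_gives_all_zero_counts_and_p_one(sim_quiet):
    from synmito import (anchors_from_orthologs, chain_anchors, merge_blocks,
                         reciprocal_best_hits, restrict_to_placed)
    res = sim_quiet
    omap = restrict_to_placed(
        reciprocal_best_hits(res.hits_ab, res.hits_ba),
        res.catalog_a, res.catalog_b)
    regions = merge_blocks(chain_anchors(
        anchors_from_orthologs(omap, res.catalog_a, res.catalog_b)))
    table, obs = movement_table(
        omap, regions, res.catalog_a, res.catalog_b, "chr1", class_filter="all")
    assert table.observed == {c: 0 for c in CATEGORIES}
    assert table.p_value == 1.0
    assert table.n_retained == len(omap)
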