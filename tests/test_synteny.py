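"""Anchor chaining, block merging and focal-region extraction."""
import numpy as np
import networkx as nx
import pytest

from synmito import (
    anchors_from_orthologs, chain_anchors, focal_syntenic_regions, merge_blocks,
    reciprocal_best_hits,
)
from synmito.orthology import OrthologMap
from synmito.synteny import SyntenyBlock, blocks_from_collinearity

from conftest import make_anchors, make_catalog


# ---------------------------------------------------------------- oracle

def nx_longest_chain(anchors, max_gap):
    """Max anchors in one monotone chain, via a DAG longest path (networkx).

    Considers both orientations; independent of the package's scored DP.
    """
    best = 0
    for sign in (1, -1):
        g = nx.DiGraph()
        g.add_nodes_from(range(len(anchors)))
        for i, ai in enumerate(anchors):
            for j, aj in enumerate(anchors):
                da = aj.rank_a - ai.rank_a
                db = sign * (aj.rank_b - ai.rank_b)
                if 0 < da <= max_gap and 0 < db <= max_gap:
                    g.add_edge(i, j)
        if len(anchors):
            best = max(best, nx.dag_longest_path_length(g) + 1)
    return best


def assert_blocks_valid(blocks, max_gap):
    seen = set()
    for b in blocks:
        ranks_a = [a.rank_a for a in b.anchors]
        ranks_b = [a.rank_b for a in b.anchors]
        assert ranks_a == sorted(ranks_a) and len(set(ranks_a)) == len(ranks_a)
        if b.orientation == "same":
            assert ranks_b == sorted(ranks_b)
        else:
            assert ranks_b == sorted(ranks_b, reverse=True)
        for (r1, s1), (r2, s2) in zip(
            zip(ranks_a, ranks_b), zip(ranks_a[1:], ranks_b[1:])
        ):
            assert 0 < r2 - r1 <= max_gap
            assert 0 < abs(s2 - s1) <= max_gap
        for a in b.anchors:
            assert a.pair not in seen  # each anchor in at most one block
            seen.add(a.pair)


# ---------------------------------------------------------------- chaining

class TestChainAnchors:
    def test_five_collinear_anchors_one_block(self):
        anchors = make_anchors([(i, i) for i in range(5)])
        (block,) = chain_anchors(anchors)
        assert len(block) == 5 and block.orientation == "same"

    def test_reversed_order_gives_inverted_block(self):
        anchors = make_anchors([(i, 4 - i) for i in range(5)])
        (block,) = chain_anchors(anchors)
        assert len(block) == 5 and block.orientation == "inverted"

    def test_below_min_anchor_threshold_no_block(self):
        anchors = make_anchors([(i, i) for i in range(4)])
        assert chain_anchors(anchors, min_block_anchors=5) == []

    def test_two_interleaved_runs_split_into_two_blocks(self):
        # runs at ranks (0,2,4,...) -> low B ranks and (1,3,5,...) -> high B
        # ranks, interleaved on A; exhaustive search says max chain is 6
        run1 = [(2 * i, i) for i in range(6)]
        run2 = [(2 * i + 1, 100 + i) for i in range(6)]
        anchors = make_anchors(run1 + run2)
        blocks = chain_anchors(anchors, min_block_anchors=5, max_gap_genes=25)
        assert sorted(len(b) for b in blocks) == [6, 6]
        assert nx_longest_chain(anchors, 25) == 6

    def test_gap_limit_breaks_chain(self):
        anchors = make_anchors([(0, 0), (1, 1), (2, 2), (30, 30), (31, 31), (32, 32)])
        blocks = chain_anchors(anchors, min_block_anchors=3, max_gap_genes=25)
        assert sorted(len(b) for b in blocks) == [3, 3]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_dag_longest_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 16))
        anchors = make_anchors([
            (int(rng.integers(0, 40)), int(rng.integers(0, 40)))
            for _ in range(n)
        ])
        # dedupe ranks on A (one gene = one rank)
        seen, uniq = set(), []
        for a in anchors:
            if a.rank_a not in seen and a.rank_b not in {u.rank_b for u in uniq}:
                uniq.append(a)
                seen.add(a.rank_a)
        blocks = chain_anchors(uniq, min_block_anchors=1, max_gap_genes=25)
        assert_blocks_valid(blocks, 25)
        assert len(blocks[0]) == nx_longest_chain(uniq, 25)


def test_anchors_from_orthologs_ranks_and_errors():
    cat_a = make_catalog("A", {"chr1": [("a1", 0, 100), ("a2", 200, 300)]})
    cat_b = make_catalog("B", {"chr2": [("b1", 50, 150), ("b2", 400, 500)]})
    omap = OrthologMap(pairs=[("a1", "b1"), ("a2", "b2")])
    anchors = anchors_from_orthologs(omap, cat_a, cat_b)
    assert [(a.rank_a, a.rank_b) for a in anchors] == [(0, 0), (1, 1)]
    with pytest.raises(ValueError, match="zz"):
        anchors_from_orthologs(OrthologMap(pairs=[("zz", "b1")]), cat_a, cat_b)


# ---------------------------------------------------------------- merging

def block_at(a_start, b_start, chrom_a="chrX", chrom_b="chr6", width=1_000_000):
    anchors = make_anchors([(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)],
                           chrom_a=chrom_a, chrom_b=chrom_b,
                           spacing=width // 5)
    shifted = [
        type(a)(pair=a.pair, chrom_a=a.chrom_a, chrom_b=a.chrom_b,
                rank_a=a.rank_a, rank_b=a.rank_b,
                span_a=(a.span_a[0] + a_start, a.span_a[1] + a_start),
                span_b=(b_start + a.span_b[0], b_start + a.span_b[1]))
        for a in anchors
    ]
    return SyntenyBlock(chrom_a, chrom_b, shifted, "same")


class TestMergeBlocks:
    def test_five_mb_gap_merges(self):
        b1 = block_at(0, 0)
        b2 = block_at(6_000_000, 6_000_000)  # ~5 Mb gap on both genomes
        (region,) = merge_blocks([b1, b2], merge_distance=10_000_000)
        assert len(region.source_blocks) == 2
        assert region.interval_a == (b1.span_a[0], b2.span_a[1])

    def test_fifteen_mb_gap_stays_split(self):
        regions = merge_blocks([block_at(0, 0), block_at(16_000_000, 16_000_000)],
                               merge_distance=10_000_000)
        assert len(regions) == 2

    def test_different_chrom_b_never_merge(self):
        regions = merge_blocks([block_at(0, 0), block_at(1_000_000, 0, chrom_b="chr7")])
        assert len(regions) == 2

    def test_gap_gate_applies_on_both_genomes(self):
        # close on A but 50 Mb apart on B -> not merged
        regions = merge_blocks([block_at(0, 0), block_at(2_000_000, 50_000_000)],
                               merge_distance=10_000_000)
        assert len(regions) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        blocks = [
            block_at(int(rng.integers(0, 80_000_000)),
                     int(rng.integers(0, 80_000_000)))
            for _ in range(int(rng.integers(2, 10)))
        ]
        once = merge_blocks(blocks)
        again = merge_blocks(
            [SyntenyBlock(r.chrom_a, r.chrom_b,
                          [a for b in r.source_blocks for a in b.anchors],
                          "same")
             for r in once]
        )
        # re-merging the merged hulls must not join or split anything
        assert sorted(r.interval_a for r in again) == sorted(
            r.interval_a for r in once)


# ---------------------------------------------------------------- focal

class TestFocalRegions:
    def test_no_region_on_focal_chromosome(self):
        cat_a = make_catalog("A", {"chrX": [("a1", 0, 100)]}, chrom_len=10_000_000)
        regions = merge_blocks([block_at(0, 0, chrom_a="chr2")])
        focal = focal_syntenic_regions(regions, "chrX", cat_a)
        assert focal.regions == [] and focal.coverage == 0.0

    def test_full_span_coverage_is_one(self):
        cat_a = make_catalog("A", {"chrX": [("a1", 0, 100)]}, chrom_len=1_000_000)
        regions = merge_blocks([block_at(0, 0)])
        # region hull spans [0, 1_000_000) after widening to chromosome size
        regions[0].interval_a = (0, 1_000_000)
        focal = focal_syntenic_regions(regions, "chrX", cat_a)
        assert focal.coverage == pytest.approx(1.0)

    def test_missing_focal_chromosome_rejected(self):
        cat_a = make_catalog("A", {"chr1": [("a1", 0, 100)]})
        with pytest.raises(ValueError, match="chrX"):
            focal_syntenic_regions([], "chrX", cat_a)

    def test_coverage_always_in_unit_interval(self, sim_quiet):
        res = sim_quiet
        omap = reciprocal_best_hits(res.hits_ab, res.hits_ba)
        from synmito import restrict_to_placed
        omap = restrict_to_placed(omap, res.catalog_a, res.catalog_b)
        anchors = anchors_from_orthologs(omap, res.catalog_a, res.catalog_b)
        regions = merge_blocks(chain_anchors(anchors))
        for chrom in res.catalog_a.chroms:
            focal = focal_syntenic_regions(regions, chrom, res.catalog_a)
            assert 0.0 <= focal.coverage <= 1.0


def test_blocks_from_collinearity_drops_unknown_anchors(caplog):
    cat_a = make_catalog("A", {"chr1": [("a1", 0, 100), ("a2", 200, 300)]})
    cat_b = make_catalog("B", {"chr2": [("b1", 0, 100), ("b2", 200, 300)]})
    records = [("chr1", "chr2", "same", [("a1", "b1"), ("aX", "b2")])]
    (block,) = blocks_from_collinearity(records, cat_a, cat_b)
    assert [a.pair for a in block.anchors] == [("a1", "b1")]
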