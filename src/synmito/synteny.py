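"""Collinear synteny blocks and their merged syntenic regions.

Ortholog pairs become anchors ranked by gene order; maximal runs of anchors
collinear on both genomes (allowing bounded gene-order gaps) form blocks,
mirroring MCScanX's defaults of at least 5 collinear genes with gaps of at
most 25 genes. Blocks on the same chromosome pair that lie closer than a
merge distance (default 10 Mb, applied to the gap on both genomes) are
merged into larger syntenic regions, reflecting the coarse-grained process
of chromosome rearrangement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import GeneCatalog
from .orthology import OrthologMap

logger = logging.getLogger(__name__)

DEFAULT_MIN_BLOCK_ANCHORS = 5
DEFAULT_MAX_GAP_GENES = 25
DEFAULT_MERGE_DISTANCE = 10_000_000

Interval = Tuple[int, int]


@dataclass(frozen=True)
class SyntenyAnchor:
    """One ortholog pair with its gene-order ranks on both chromosomes."""

    pair: Tuple[str, str]
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    span_a: Interval
    span_b: Interval


@dataclass
class SyntenyBlock:
    """A maximal collinear run of anchors on one chromosome pair."""

    chrom_a: str
    chrom_b: str
    anchors: List[SyntenyAnchor]
    orientation: str  # "same" | "inverted"

    @property
    def span_a(self) -> Interval:
        return (min(a.span_a[0] for a in self.anchors),
                max(a.span_a[1] for a in self.anchors))

    @property
    def span_b(self) -> Interval:
        return (min(a.span_b[0] for a in self.anchors),
                max(a.span_b[1] for a in self.anchors))

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class MergedRegion:
    """The hull of one or more nearby blocks on a chromosome pair."""

    chrom_a: str
    chrom_b: str
    interval_a: Interval
    interval_b: Interval
    source_blocks: List[SyntenyBlock] = field(default_factory=list)

    @property
    def n_anchors(self) -> int:
        return sum(len(b) for b in self.source_blocks)

    def contains_a(self, midpoint: int, chrom: str) -> bool:
        return chrom == self.chrom_a and self.interval_a[0] <= midpoint < self.interval_a[1]

    def contains_b(self, midpoint: int, chrom: str) -> bool:
        return chrom == self.chrom_b and self.interval_b[0] <= midpoint < self.interval_b[1]


def anchors_from_orthologs(
    omap: OrthologMap, catalog_a: GeneCatalog, catalog_b: GeneCatalog
) -> List[SyntenyAnchor]:
    """One anchor per ortholog pair, ranked by start-sorted gene order."""
    ranks_a = catalog_a.gene_ranks()
    ranks_b = catalog_b.gene_ranks()
    anchors: List[SyntenyAnchor] = []
    for a, b in omap.pairs:
        ga, gb = catalog_a.get(a), catalog_b.get(b)
        if ga is None or gb is None:
            missing = a if ga is None else b
            raise ValueError(f"anchor gene {missing!r} has no coordinates in its catalog")
        if not (ga.placed and gb.placed):
            raise ValueError(f"anchor pair ({a}, {b}) includes an unplaced gene")
        anchors.append(SyntenyAnchor(
            pair=(a, b), chrom_a=ga.chrom, chrom_b=gb.chrom,
            rank_a=ranks_a[a], rank_b=ranks_b[b],
            span_a=(ga.start, ga.end), span_b=(gb.start, gb.end),
        ))
    return anchors


def _best_chain(
    anchors: Sequence[SyntenyAnchor], orientation: str, max_gap: int
) -> List[int]:
    """Indices of the maximum-anchor chain, strictly monotone in both ranks.

    Same-orientation chains increase in rank_b; inverted chains decrease.
    Consecutive anchors may differ by at most ``max_gap`` in either rank.
    Deterministic tie-breaks: prefer predecessors and endpoints with smaller
    rank_a, then smaller rank_b.
    """
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    sign = 1 if orientation == "same" else -1
    length = [1] * len(order)
    parent: List[Optional[int]] = [None] * len(order)
    for pos, i in enumerate(order):
        ai = anchors[i]
        for qos in range(pos):
            j = order[qos]
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            db = sign * (ai.rank_b - aj.rank_b)
            if 0 < da <= max_gap and 0 < db <= max_gap:
                cand = length[qos] + 1
                if cand > length[pos]:
                    length[pos] = cand
                    parent[pos] = qos
        # ties resolved implicitly: earlier (smaller-rank) predecessors win
    best_pos = max(range(len(order)), key=lambda p: (length[p], -anchors[order[p]].rank_a,
                                                     -anchors[order[p]].rank_b))
    chain: List[int] = []
    pos: Optional[int] = best_pos
    while pos is not None:
        chain.append(order[pos])
        pos = parent[pos]
    chain.reverse()
    return chain


def chain_anchors(
    anchors: Iterable[SyntenyAnchor],
    min_block_anchors: int = DEFAULT_MIN_BLOCK_ANCHORS,
    max_gap_genes: int = DEFAULT_MAX_GAP_GENES,
) -> List[SyntenyBlock]:
    """Greedy extraction of maximal collinear chains into synteny blocks.

    Within each chromosome pair the longest chain (same or inverted
    orientation) is extracted, its anchors removed, and the search repeated
    until no chain reaches ``min_block_anchors``. Each anchor therefore
    belongs to at most one block. Output is ordered by descending anchor
    count, then leftmost genome-A interval, then chromosome pair.
    """
    groups: Dict[Tuple[str, str], List[SyntenyAnchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: List[SyntenyBlock] = []
    for (ca, cb), group in sorted(groups.items()):
        remaining = list(group)
        while len(remaining) >= min_block_anchors:
            same = _best_chain(remaining, "same", max_gap_genes)
            inv = _best_chain(remaining, "inverted", max_gap_genes)
            if len(same) >= len(inv):
                chain, orientation = same, "same"
            else:
                chain, orientation = inv, "inverted"
            if len(chain) < min_block_anchors:
                break
            chosen = set(chain)
            blocks.append(SyntenyBlock(
                chrom_a=ca, chrom_b=cb,
                anchors=[remaining[i] for i in chain],
                orientation=orientation,
            ))
            remaining = [a for i, a in enumerate(remaining) if i not in chosen]
    blocks.sort(key=lambda b: (-len(b), b.span_a[0], b.chrom_a, b.chrom_b))
    return blocks


def blocks_from_collinearity(
    records, catalog_a: GeneCatalog, catalog_b: GeneCatalog
) -> List[SyntenyBlock]:
    """Validate raw collinearity records against catalogs.

    Anchors whose genes are missing from either catalog are dropped with a
    logged count; blocks losing all anchors are discarded.
    """
    ranks_a = catalog_a.gene_ranks()
    ranks_b = catalog_b.gene_ranks()
    blocks: List[SyntenyBlock] = []
    n_dropped = 0
    for chrom_a, chrom_b, orientation, pairs in records:
        anchors: List[SyntenyAnchor] = []
        for a, b in pairs:
            ga, gb = catalog_a.get(a), catalog_b.get(b)
            if ga is None or gb is None:
                n_dropped += 1
                continue
            anchors.append(SyntenyAnchor(
                pair=(a, b), chrom_a=ga.chrom, chrom_b=gb.chrom,
                rank_a=ranks_a[a], rank_b=ranks_b[b],
                span_a=(ga.start, ga.end), span_b=(gb.start, gb.end),
            ))
        if anchors:
            blocks.append(SyntenyBlock(chrom_a, chrom_b, anchors, orientation))
    if n_dropped:
        logger.warning("dropped %d collinearity anchors absent from catalogs", n_dropped)
    return blocks


def _gap(iv1: Interval, iv2: Interval) -> int:
    """Distance between two intervals; 0 when they touch or overlap."""
    return max(iv1[0], iv2[0]) - min(iv1[1], iv2[1]) if (
        iv1[1] < iv2[0] or iv2[1] < iv1[0]
    ) else 0


def _hull(iv1: Interval, iv2: Interval) -> Interval:
    return (min(iv1[0], iv2[0]), max(iv1[1], iv2[1]))


def merge_blocks(
    blocks: Iterable[SyntenyBlock],
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
) -> List[MergedRegion]:
    """Merge blocks on one chromosome pair closer than ``merge_distance``.

    Blocks are sorted by genome-A start and absorbed transitively into the
    growing region whenever the gaps to the region's hull are below the
    threshold on *both* genomes; requiring both sides prevents chimeric
    regions joining distant genome-B segments.
    """
    groups: Dict[Tuple[str, str], List[SyntenyBlock]] = {}
    for b in blocks:
        groups.setdefault((b.chrom_a, b.chrom_b), []).append(b)
    regions: List[MergedRegion] = []
    for (ca, cb), group in sorted(groups.items()):
        group = sorted(group, key=lambda b: (b.span_a[0], b.span_a[1]))
        current: Optional[MergedRegion] = None
        for blk in group:
            if current is None:
                current = MergedRegion(ca, cb, blk.span_a, blk.span_b, [blk])
                continue
            gap_a = _gap(current.interval_a, blk.span_a)
            gap_b = _gap(current.interval_b, blk.span_b)
            if gap_a < merge_distance and gap_b < merge_distance:
                current.interval_a = _hull(current.interval_a, blk.span_a)
                current.interval_b = _hull(current.interval_b, blk.span_b)
                current.source_blocks.append(blk)
            else:
                regions.append(current)
                current = MergedRegion(ca, cb, blk.span_a, blk.span_b, [blk])
        if current is not None:
            regions.append(current)
    regions.sort(key=lambda r: (r.chrom_a, r.interval_a[0], r.chrom_b))
    return regions


@dataclass
class FocalSynteny:
    """Regions of genome B syntenic to one focal genome-A chromosome."""

    focal_chrom_a: str
    regions: List[MergedRegion]
    coverage: float  # fraction of the focal chromosome covered on genome A

    @property
    def chroms_b(self) -> List[str]:
        return sorted({r.chrom_b for r in self.regions})


def focal_syntenic_regions(
    merged: Iterable[MergedRegion],
    focal_chrom_a: str,
    catalog_a: GeneCatalog,
) -> FocalSynteny:
    """Extract the merged regions lying on the focal genome-A chromosome.

    Coverage is the fraction of the focal chromosome's length covered by
    the union of the regions' genome-A intervals.
    """
    if focal_chrom_a not in catalog_a.chrom_lengths:
        raise ValueError(
            f"focal chromosome {focal_chrom_a!r} absent from catalog "
            f"{catalog_a.genome_label!r}"
        )
    regions = [r for r in merged if r.chrom_a == focal_chrom_a]
    ivs = sorted(r.interval_a for r in regions)
    covered = 0
    end = -1
    for s, e in ivs:
        s = max(s, end)
        if e > s:
            covered += e - s
            end = e
        end = max(end, e)
    coverage = covered / catalog_a.chrom_lengths[focal_chrom_a]
    return FocalSynteny(focal_chrom_a, regions, coverage)
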