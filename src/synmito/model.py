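"""Core domain types: genes, genome catalogs, and homology hits.

All coordinates are 0-based, half-open internally; conversion to and from
1-based closed conventions (GFF3) happens only at IO boundaries.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional


@dataclass(frozen=True)
class Gene:
    """A single gene placed on a chromosome or scaffold.

    ``is_mtn`` flags mitonuclear genes (nuclear genes whose product acts in
    the mitochondrion, GO:0005739). ``placed`` marks genes on sequences large
    enough to infer synteny from; unplaced genes are excluded from anchor
    construction but still count in genome totals.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    is_mtn: bool = False
    placed: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GeneCatalog:
    """All genes of one genome plus its chromosome lengths.

    Gene ids are unique; every gene's chromosome must appear in
    ``chrom_lengths`` and be long enough to contain the gene.
    """

    def __init__(
        self,
        genome_label: str,
        genes: Iterable[Gene],
        chrom_lengths: Dict[str, int],
    ) -> None:
        self.genome_label = genome_label
        self.chrom_lengths = dict(chrom_lengths)
        self.genes: List[Gene] = []
        self._by_id: Dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in catalog {genome_label!r}")
            if g.chrom not in self.chrom_lengths:
                raise ValueError(
                    f"gene {g.gene_id}: chromosome {g.chrom!r} missing from lengths table"
                )
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} exceeds length of {g.chrom} "
                    f"({self.chrom_lengths[g.chrom]})"
                )
            self.genes.append(g)
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def get(self, gene_id: str) -> Optional[Gene]:
        return self._by_id.get(gene_id)

    @property
    def chroms(self) -> List[str]:
        return sorted(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def genes_on(self, chrom: str) -> List[Gene]:
        """Genes on one chromosome, sorted by start (ties by id)."""
        return sorted(
            (g for g in self.genes if g.chrom == chrom),
            key=lambda g: (g.start, g.gene_id),
        )

    def gene_ranks(self) -> Dict[str, int]:
        """0-based position of every gene in its chromosome's start-sorted order."""
        ranks: Dict[str, int] = {}
        for chrom in self.chroms:
            for i, g in enumerate(self.genes_on(chrom)):
                ranks[g.gene_id] = i
        return ranks

    def with_mtn_flags(self, mtn_ids: Iterable[str]) -> "GeneCatalog":
        """Return a copy with ``is_mtn`` set from a set of gene ids."""
        mtn = set(mtn_ids)
        return GeneCatalog(
            self.genome_label,
            (replace(g, is_mtn=g.gene_id in mtn) for g in self.genes),
            self.chrom_lengths,
        )

    def with_placed_pattern(self, pattern: Optional[str]) -> "GeneCatalog":
        """Return a copy with ``placed`` = (chromosome name matches regex).

        ``None`` marks every gene placed. Which sequences count as "large
        enough for synteny" is assembly-specific metadata, so it is supplied
        as a pattern rather than hard-coded.
        """
        if pattern is None:
            flagged = (replace(g, placed=True) for g in self.genes)
        else:
            rx = re.compile(pattern)
            flagged = (
                replace(g, placed=bool(rx.match(g.chrom))) for g in self.genes
            )
        return GeneCatalog(self.genome_label, flagged, self.chrom_lengths)

    @property
    def n_mtn(self) -> int:
        return sum(g.is_mtn for g in self.genes)


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise protein homology hit (one row of BLAST tabular output)."""

    query_id: str
    subject_id: str
    pct_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query_id}->{self.subject_id}")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(
                f"identity {self.pct_identity} outside [0, 100] for "
                f"{self.query_id}->{self.subject_id}"
            )
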