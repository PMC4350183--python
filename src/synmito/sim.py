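"""Two-lineage genome-evolution simulator with a replayable truth log.

An ancestral genome is laid out gene by gene with exponential intergenic
gaps; a labelled gene class (the mitonuclear analogue) is drawn per
chromosome with configurable density biases. Two descendant genomes then
evolve independently by interval inversions, interval translocations and
single-gene relocations whose rate can be biased by direction relative to
a focal chromosome (the X analogue). The simulator emits every input
format the analysis pipeline consumes — BED gene tables, chromosome
lengths, mutual homology-hit tables with paralog noise, GO-style
annotation — plus a JSON truth log of ortholog pairs, events and the true
focal-syntenic map.

All randomness flows through a single generator seeded from the config;
draw order is fixed (ancestor → lineage A → lineage B → hits), so outputs
are bit-reproducible.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import Gene, GeneCatalog
from . import io as sio

FOCAL_CHROM = "chr1"

MOVE_CATEGORIES = ("off_focal", "onto_focal", "autosome_autosome")


@dataclass
class SimConfig:
    """Study conditions for one simulated genome pair.

    Defaults emulate a small amniote-like genome: ~1,000 genes on 8
    chromosomes at one gene per ~30 kb, a mitonuclear class at 8% of genes
    (the human proportion is 1,572 of ~20,000), and a focal chromosome
    holding ~1/8 of the genome, standing in for the X.
    """

    n_chroms: int = 8
    genes_per_chrom: Optional[Tuple[int, ...]] = None  # default: 120 each
    mtn_fraction: float = 0.08
    per_chrom_mtn_bias: Optional[Tuple[float, ...]] = None  # default: all 1
    n_inversions: int = 3
    n_translocations: int = 1
    move_rate: float = 0.01
    move_bias: Dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in MOVE_CATEGORIES}
    )
    mean_gene_len: int = 3_000
    mean_intergenic: int = 27_000
    paralog_rate: float = 0.05
    identity_mean: float = 70.0
    identity_sd: float = 10.0
    annotation_agreement: float = 0.9
    ultra_split_chroms: int = 0  # B chromosomes (from chr1) split into Ultra contigs
    ultra_pieces: int = 3
    scaffold_fraction: float = 0.0  # B genes stranded on tiny unplaced scaffolds
    seed: int = 0

    def resolved_genes_per_chrom(self) -> Tuple[int, ...]:
        if self.genes_per_chrom is not None:
            if len(self.genes_per_chrom) != self.n_chroms:
                raise ValueError("genes_per_chrom length must equal n_chroms")
            return tuple(self.genes_per_chrom)
        return tuple([120] * self.n_chroms)

    def resolved_mtn_bias(self) -> Tuple[float, ...]:
        counts = np.array(self.resolved_genes_per_chrom(), dtype=float)
        if self.per_chrom_mtn_bias is None:
            raw = np.ones(self.n_chroms)
        else:
            if len(self.per_chrom_mtn_bias) != self.n_chroms:
                raise ValueError("per_chrom_mtn_bias length must equal n_chroms")
            raw = np.array(self.per_chrom_mtn_bias, dtype=float)
            if np.any(raw < 0):
                raise ValueError("per-chromosome biases must be >= 0")
        # renormalize to gene-weighted mean 1 so mtn_fraction is genome-wide
        raw = raw / float(np.average(raw, weights=counts))
        if np.any(raw * self.mtn_fraction > 1.0):
            raise ValueError("bias vector forces a per-gene probability > 1")
        return tuple(float(x) for x in raw)


@dataclass
class TruthLog:
    """Replayable record of everything the simulator did."""

    ortholog_pairs: List[Tuple[str, str]] = field(default_factory=list)
    movements: List[Dict] = field(default_factory=list)
    rearrangements: List[Dict] = field(default_factory=list)
    per_chrom_mtn_bias: Dict[str, float] = field(default_factory=dict)
    focal_syntenic_b: List[Tuple[str, int, int]] = field(default_factory=list)
    unplaced_genes: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLog":
        d = json.loads(text)
        log = cls()
        log.ortholog_pairs = [tuple(p) for p in d["ortholog_pairs"]]
        log.movements = d["movements"]
        log.rearrangements = d["rearrangements"]
        log.per_chrom_mtn_bias = d["per_chrom_mtn_bias"]
        log.focal_syntenic_b = [tuple(r) for r in d["focal_syntenic_b"]]
        log.unplaced_genes = d["unplaced_genes"]
        return log


# internal gene record: (ancestral id, length, is_mtn, strand)
_Rec = Tuple[str, int, bool, str]


def _layout(
    order: Dict[str, List[_Rec]],
    rng: np.random.Generator,
    config: SimConfig,
    label: str,
    id_prefix: str = "",
) -> GeneCatalog:
    """Assign coordinates chromosome by chromosome with exponential gaps."""
    genes: List[Gene] = []
    lengths: Dict[str, int] = {}
    for chrom in sorted(order):
        pos = 0
        for gid, glen, is_mtn, strand in order[chrom]:
            gap = int(rng.exponential(config.mean_intergenic)) + 1
            start = pos + gap
            end = start + glen
            genes.append(Gene(id_prefix + gid, chrom, start, end, strand, is_mtn=is_mtn))
            pos = end
        lengths[chrom] = pos + int(rng.exponential(config.mean_intergenic)) + 1
    return GeneCatalog(label, genes, lengths)


def simulate_ancestor(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> GeneCatalog:
    """Draw the ancestral genome: placements, lengths and class flags."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = config.resolved_genes_per_chrom()
    biases = config.resolved_mtn_bias()
    order: Dict[str, List[_Rec]] = {}
    idx = 0
    for c, (n, b) in enumerate(zip(counts, biases), start=1):
        chrom = f"chr{c}"
        recs: List[_Rec] = []
        for _ in range(n):
            gid = f"g{idx:05d}"
            idx += 1
            glen = int(rng.exponential(config.mean_gene_len)) + 200
            is_mtn = bool(rng.random() < config.mtn_fraction * b)
            strand = "+" if rng.random() < 0.5 else "-"
            recs.append((gid, glen, is_mtn, strand))
        order[chrom] = recs
    return _layout(order, rng, config, "ancestor")


def _order_from_catalog(catalog: GeneCatalog) -> Dict[str, List[_Rec]]:
    return {
        chrom: [(g.gene_id, g.end - g.start, g.is_mtn, g.strand)
                for g in catalog.genes_on(chrom)]
        for chrom in catalog.chroms
    }


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, strand)


def evolve_descendant(
    ancestor: GeneCatalog,
    config: SimConfig,
    lineage_label: str,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[GeneCatalog, List[Dict], List[Dict]]:
    """Evolve one descendant; returns (catalog, movements, rearrangements).

    Order of operations: inversions, then translocations, then single-gene
    relocations. Relocation destinations are drawn in proportion to current
    chromosome gene content, then accepted with a probability scaled by the
    direction-specific multiplier in ``config.move_bias`` — an unbiased
    config reproduces the size-and-content null the movement test assumes.
    Descendant gene ids are namespaced ``<lineage>_<ancestral id>``.
    """
    if rng is None:
        # stable per-lineage stream (process hash randomization would break replay)
        tag = sum(ord(c) for c in lineage_label) % (2**31)
        rng = np.random.default_rng((config.seed, tag))
    order = _order_from_catalog(ancestor)
    chroms = sorted(order)
    rearrangements: List[Dict] = []
    movements: List[Dict] = []

    max_mult = max(config.move_bias.get(c, 1.0) for c in MOVE_CATEGORIES)
    if max_mult > 0 and config.move_rate * max_mult > 1.0:
        raise ValueError("move_rate times the largest move_bias exceeds 1")

    for _ in range(config.n_inversions):
        chrom = chroms[rng.integers(len(chroms))]
        recs = order[chrom]
        if len(recs) < 2:
            rearrangements.append({"op": "inversion", "chrom": chrom, "skipped": True})
            continue
        span = int(rng.integers(2, min(20, len(recs)) + 1))
        i = int(rng.integers(0, len(recs) - span + 1))
        j = i + span
        order[chrom] = (
            recs[:i]
            + [(gid, glen, m, _flip(s)) for gid, glen, m, s in reversed(recs[i:j])]
            + recs[j:]
        )
        rearrangements.append(
            {"op": "inversion", "lineage": lineage_label, "chrom": chrom,
             "first": i, "last": j - 1}
        )

    for _ in range(config.n_translocations):
        src = chroms[rng.integers(len(chroms))]
        recs = order[src]
        if len(recs) < 7:
            rearrangements.append({"op": "translocation", "chrom": src, "skipped": True})
            continue
        span = int(rng.integers(5, min(15, len(recs) - 1) + 1))
        i = int(rng.integers(0, len(recs) - span + 1))
        segment = recs[i:i + span]
        order[src] = recs[:i] + recs[i + span:]
        others = [c for c in chroms if c != src]
        dst = others[rng.integers(len(others))]
        at = int(rng.integers(0, len(order[dst]) + 1))
        order[dst] = order[dst][:at] + segment + order[dst][at:]
        rearrangements.append(
            {"op": "translocation", "lineage": lineage_label, "src": src,
             "dst": dst, "n_genes": span, "genes": [r[0] for r in segment]}
        )

    if config.move_rate > 0:
        snapshot = [(chrom, rec) for chrom in chroms for rec in list(order[chrom])]
        pending: List[Tuple[str, str, _Rec]] = []
        for src, rec in snapshot:
            weights = np.array(
                [len(order[c]) if c != src else 0 for c in chroms], dtype=float
            )
            if weights.sum() == 0:
                continue
            dst = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
            if src == FOCAL_CHROM:
                cat = "off_focal"
            elif dst == FOCAL_CHROM:
                cat = "onto_focal"
            else:
                cat = "autosome_autosome"
            if rng.random() < config.move_rate * config.move_bias.get(cat, 1.0):
                pending.append((src, dst, rec))
                movements.append(
                    {"gene": rec[0], "lineage": lineage_label, "src_chrom": src,
                     "dst_chrom": dst, "category": cat, "is_mtn": rec[2]}
                )
        for src, dst, rec in pending:
            order[src] = [r for r in order[src] if r[0] != rec[0]]
            at = int(rng.integers(0, len(order[dst]) + 1))
            order[dst] = order[dst][:at] + [rec] + order[dst][at:]

    catalog = _layout(order, rng, config, lineage_label, id_prefix=f"{lineage_label}_")
    return catalog, movements, rearrangements


def _split_ultras(
    catalog: GeneCatalog, config: SimConfig, rng: np.random.Generator
) -> GeneCatalog:
    """Split the first ``ultra_split_chroms`` chromosomes into Ultra contigs.

    Emulates an assembly whose large pieces are unassigned contigs rather
    than chromosomes (the monotreme situation): gene content and order are
    preserved, only the naming and coordinate origin change.
    """
    if config.ultra_split_chroms <= 0:
        return catalog
    order = _order_from_catalog(catalog)
    targets = [f"chr{i}" for i in range(1, config.ultra_split_chroms + 1)]
    new_order: Dict[str, List[_Rec]] = {}
    n_ultra = 0
    for chrom in sorted(order):
        if chrom in targets and len(order[chrom]) >= config.ultra_pieces:
            cuts = np.array_split(np.arange(len(order[chrom])), config.ultra_pieces)
            for piece in cuts:
                n_ultra += 1
                new_order[f"Ultra{n_ultra}"] = [order[chrom][i] for i in piece]
        else:
            new_order[chrom] = order[chrom]
    return _layout(new_order, rng, config, catalog.genome_label)


def _strand_scaffolds(
    catalog: GeneCatalog, config: SimConfig, rng: np.random.Generator
) -> Tuple[GeneCatalog, List[str]]:
    """Move a fraction of genes onto tiny single-gene unplaced scaffolds."""
    if config.scaffold_fraction <= 0:
        return catalog, []
    order = _order_from_catalog(catalog)
    stranded: List[str] = []
    n_scaf = 0
    for chrom in sorted(order):
        kept: List[_Rec] = []
        for rec in order[chrom]:
            if rng.random() < config.scaffold_fraction:
                n_scaf += 1
                order_key = f"scaffold{n_scaf}"
                order[order_key] = [rec]
                stranded.append(rec[0])
            else:
                kept.append(rec)
        order[chrom] = kept
    out = _layout(order, rng, config, catalog.genome_label)
    out = out.with_placed_pattern(r"^(chr|Ultra)")
    return out, stranded


def _true_focal_map(
    catalog_a: GeneCatalog, catalog_b: GeneCatalog, pairs: Sequence[Tuple[str, str]]
) -> List[Tuple[str, int, int]]:
    """Hulls, on genome B, of runs of genes whose ortholog is focal on A."""
    on_focal_b = {
        b for a, b in pairs
        if catalog_a.get(a) is not None and catalog_a[a].chrom == FOCAL_CHROM
    }
    out: List[Tuple[str, int, int]] = []
    for chrom in catalog_b.chroms:
        run: List[Gene] = []
        for g in catalog_b.genes_on(chrom):
            if g.gene_id in on_focal_b:
                run.append(g)
            else:
                if len(run) >= 5:
                    out.append((chrom, run[0].start, run[-1].end))
                run = []
        if len(run) >= 5:
            out.append((chrom, run[0].start, run[-1].end))
    return out


def emit_hits(
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    pairs: Sequence[Tuple[str, str]],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Emulate mutual protein homology searches for the true ortholog pairs.

    Each true pair gets a strong reciprocal hit (identity drawn near
    ``identity_mean``, truncated to (30, 100]); paralog noise adds weaker
    unilateral hits at ``paralog_rate`` per gene. E-values decrease
    monotonically with bitscore. Returns (hits_a_to_b, hits_b_to_a).
    """
    from .model import HomologyHit

    if rng is None:
        rng = np.random.default_rng((config.seed, 3))

    def _evalue(bitscore: float) -> float:
        return 10.0 ** (-bitscore / 10.0)

    hits_ab: List[HomologyHit] = []
    hits_ba: List[HomologyHit] = []
    for a, b in pairs:
        bit = float(max(150.0, rng.normal(500.0, 30.0)))
        ident = float(min(100.0, max(30.01, rng.normal(config.identity_mean,
                                                       config.identity_sd))))
        hits_ab.append(HomologyHit(a, b, ident, _evalue(bit), bit))
        hits_ba.append(HomologyHit(b, a, ident, _evalue(bit), bit))
    if config.paralog_rate > 0:
        b_ids = [g.gene_id for g in catalog_b.genes]
        a_ids = [g.gene_id for g in catalog_a.genes]
        for a, _ in pairs:
            if rng.random() < config.paralog_rate:
                b2 = b_ids[rng.integers(len(b_ids))]
                bit = float(rng.uniform(120.0, 400.0))
                ident = float(min(95.0, max(20.0, rng.normal(
                    config.identity_mean - 15.0, config.identity_sd))))
                hits_ab.append(HomologyHit(a, b2, ident, _evalue(bit), bit))
        for _, b in pairs:
            if rng.random() < config.paralog_rate:
                a2 = a_ids[rng.integers(len(a_ids))]
                bit = float(rng.uniform(120.0, 400.0))
                ident = float(min(95.0, max(20.0, rng.normal(
                    config.identity_mean - 15.0, config.identity_sd))))
                hits_ba.append(HomologyHit(b, a2, ident, _evalue(bit), bit))
    return hits_ab, hits_ba


@dataclass
class SimResult:
    """Everything one simulation run produced, in memory."""

    config: SimConfig
    catalog_a: GeneCatalog
    catalog_b: GeneCatalog
    hits_ab: list
    hits_ba: list
    truth: TruthLog


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: ancestor, two descendants, hits, truth log."""
    rng = np.random.default_rng(config.seed)
    ancestor = simulate_ancestor(config, rng)

    catalog_a, moves_a, rearr_a = evolve_descendant(ancestor, config, "A", rng)
    catalog_b, moves_b, rearr_b = evolve_descendant(ancestor, config, "B", rng)
    catalog_b = _split_ultras(catalog_b, config, rng)
    catalog_b, stranded = _strand_scaffolds(catalog_b, config, rng)

    # descendant ids share the ancestral suffix: A_g00012 <-> B_g00012
    pairs = sorted(
        (f"A_{gid}", f"B_{gid}")
        for gid in (g.gene_id[2:] for g in catalog_a.genes)
        if f"B_{gid}" in catalog_b
    )

    truth = TruthLog()
    truth.ortholog_pairs = pairs
    truth.movements = moves_a + moves_b
    truth.rearrangements = rearr_a + rearr_b
    counts = config.resolved_genes_per_chrom()
    biases = config.resolved_mtn_bias()
    truth.per_chrom_mtn_bias = {
        f"chr{i + 1}": biases[i] for i in range(len(counts))
    }
    truth.focal_syntenic_b = _true_focal_map(catalog_a, catalog_b, pairs)
    truth.unplaced_genes = list(stranded)  # already lineage-prefixed ids

    hits_ab, hits_ba = emit_hits(catalog_a, catalog_b, pairs, config, rng)
    return SimResult(config, catalog_a, catalog_b, hits_ab, hits_ba, truth)


def emit_fixtures(config: SimConfig, outdir: str) -> Dict[str, str]:
    """Run the simulator and write every pipeline input file to ``outdir``.

    Writes A.bed / B.bed, *.lengths.tsv, A_B.tsv / B_A.tsv hit tables,
    mtn_A.tsv / mtn_B.tsv GO-style annotations, and truth.json. Returns a
    name → path map.
    """
    os.makedirs(outdir, exist_ok=True)
    res = simulate(config)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("genes_a", "A.bed"), ("genes_b", "B.bed"),
        ("lengths_a", "A.lengths.tsv"), ("lengths_b", "B.lengths.tsv"),
        ("hits_ab", "A_B.tsv"), ("hits_ba", "B_A.tsv"),
        ("mtn_a", "mtn_A.tsv"), ("mtn_b", "mtn_B.tsv"),
        ("truth", "truth.json"),
    ]}
    sio.write_gene_table(res.catalog_a, paths["genes_a"], "BED")
    sio.write_gene_table(res.catalog_b, paths["genes_b"], "BED")
    sio.write_chrom_lengths(res.catalog_a.chrom_lengths, paths["lengths_a"])
    sio.write_chrom_lengths(res.catalog_b.chrom_lengths, paths["lengths_b"])
    sio.write_hit_table(res.hits_ab, paths["hits_ab"])
    sio.write_hit_table(res.hits_ba, paths["hits_ba"])
    sio.write_go_annotations(
        (g.gene_id for g in res.catalog_a.genes if g.is_mtn), paths["mtn_a"]
    )
    # species-B annotation: imperfect agreement with the ortholog-derived flags
    rng = np.random.default_rng((config.seed, 7))
    mtn_b = []
    for g in res.catalog_b.genes:
        if g.is_mtn and rng.random() < config.annotation_agreement:
            mtn_b.append(g.gene_id)
        elif not g.is_mtn and rng.random() < (
            (1.0 - config.annotation_agreement) * config.mtn_fraction
        ):
            mtn_b.append(g.gene_id)
    sio.write_go_annotations(mtn_b, paths["mtn_b"])
    with open(paths["truth"], "w") as fh:
        fh.write(res.truth.to_json())
    return paths
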