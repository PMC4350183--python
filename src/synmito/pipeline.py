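"""End-to-end orchestration: orthology → synteny → movement → abundance.

``run_all`` reads every input named in a :class:`RunConfig`, executes the
four analysis stages and writes a reproducible TSV report bundle:
``regions.tsv`` (merged syntenic regions), ``movement.tsv`` (observed vs
expected movement counts with the exact-test p), ``bias.tsv`` (per-region
mitonuclear density with bootstrap CIs) and ``run.log``. Given a fixed
seed the bundle is byte-identical across runs.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import yaml

from . import io as sio
from . import __version__
from .abundance import BiasResult, flag_overlap, region_bias, region_fisher
from .model import Gene, GeneCatalog
from .movement import CATEGORIES, MovementObservation, MovementTable, movement_table
from .orthology import (
    DEFAULT_MAX_EVALUE,
    DEFAULT_MIN_IDENTITY,
    OrthologMap,
    reciprocal_best_hits,
    restrict_to_placed,
)
from .synteny import (
    DEFAULT_MAX_GAP_GENES,
    DEFAULT_MERGE_DISTANCE,
    DEFAULT_MIN_BLOCK_ANCHORS,
    FocalSynteny,
    MergedRegion,
    anchors_from_orthologs,
    chain_anchors,
    focal_syntenic_regions,
    merge_blocks,
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and thresholds for one full pipeline run.

    Threshold defaults are the analysis constants: e-value < 1e-10 and top
    hit identity > 30% for orthology, blocks of >= 5 anchors with gene-order
    gaps <= 25, a 10 Mb block-merge distance, and 10,000 bootstrap
    resamples for the bias CIs.
    """

    genes_a: str = ""
    genes_b: str = ""
    lengths_a: str = ""
    lengths_b: str = ""
    hits_ab: str = ""
    hits_ba: str = ""
    mtn_a: str = ""
    mtn_b: str = ""  # optional; needed only for annotation-mode flags
    gene_format: str = "BED"
    focal_chrom_a: str = "chr1"
    placed_pattern_a: Optional[str] = None
    placed_pattern_b: Optional[str] = None
    max_evalue: float = DEFAULT_MAX_EVALUE
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_block_anchors: int = DEFAULT_MIN_BLOCK_ANCHORS
    max_gap_genes: int = DEFAULT_MAX_GAP_GENES
    merge_distance: int = DEFAULT_MERGE_DISTANCE
    n_boot: int = 10_000
    seed: int = 0
    mtn_mode: str = "orthology"  # or "annotation"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        required = ["genes_a", "genes_b", "lengths_a", "lengths_b",
                    "hits_ab", "hits_ba", "mtn_a"]
        if self.mtn_mode == "annotation":
            required.append("mtn_b")
        for name in required:
            path = getattr(self, name)
            if not path:
                raise ValueError(f"config field {name!r} is required")
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name}: no such file {path!r}")
        for name in ("max_evalue", "min_block_anchors", "max_gap_genes",
                     "merge_distance", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name!r} must be positive")


@dataclass
class RunResult:
    """In-memory bundle of everything one pipeline run computed."""

    catalog_a: GeneCatalog
    catalog_b: GeneCatalog
    orthologs: OrthologMap
    orthologs_placed: OrthologMap
    regions: List[MergedRegion]
    focal: FocalSynteny
    movement: MovementTable
    movement_obs: MovementObservation
    biases: List[BiasResult]
    abundance_p: Optional[float]
    mtn_overlap: Optional[float]
    log_lines: List[str] = field(default_factory=list)


def _genes_in_regions_a(catalog: GeneCatalog, regions: Sequence[MergedRegion]) -> List[Gene]:
    return [g for g in catalog.genes
            if any(r.contains_a(g.midpoint, g.chrom) for r in regions)]


def _genes_in_regions_b(catalog: GeneCatalog, regions: Sequence[MergedRegion]) -> List[Gene]:
    return [g for g in catalog.genes
            if any(r.contains_b(g.midpoint, g.chrom) for r in regions)]


def run_all(config: RunConfig) -> RunResult:
    """Execute the full analysis and return the in-memory result bundle."""
    log: List[str] = [f"synmito {__version__}", f"seed {config.seed}",
                      f"mtn_mode {config.mtn_mode}"]

    try:
        catalog_a = sio.read_gene_table(
            config.genes_a, config.gene_format, config.lengths_a, "A"
        ).with_placed_pattern(config.placed_pattern_a)
        catalog_b = sio.read_gene_table(
            config.genes_b, config.gene_format, config.lengths_b, "B"
        ).with_placed_pattern(config.placed_pattern_b)
        mtn_a_ids = sio.read_go_annotations(config.mtn_a)
        catalog_a = catalog_a.with_mtn_flags(mtn_a_ids)
        hits_ab = sio.read_hit_table(config.hits_ab)
        hits_ba = sio.read_hit_table(config.hits_ba)
    except Exception as exc:
        raise PipelineError("read_inputs", exc) from exc
    log.append(f"genes A {len(catalog_a)} (mt-N {catalog_a.n_mtn}), "
               f"B {len(catalog_b)}")

    try:
        omap = reciprocal_best_hits(
            hits_ab, hits_ba, config.max_evalue, config.min_identity
        )
        omap_placed = restrict_to_placed(omap, catalog_a, catalog_b)
    except Exception as exc:
        raise PipelineError("orthology", exc) from exc
    log.append(f"rBBH pairs {len(omap)}, placed {len(omap_placed)}")

    # mitonuclear flags on genome B: via orthology to flagged A genes, or
    # from genome B's own annotation file
    mtn_overlap = None
    ortho_mtn_b = {b for a, b in omap.pairs if a in mtn_a_ids}
    if config.mtn_mode == "annotation":
        mtn_b_ids = sio.read_go_annotations(config.mtn_b)
        mtn_overlap = flag_overlap(ortho_mtn_b, mtn_b_ids)
        log.append(f"mt-N flag overlap (orthology vs annotation) {mtn_overlap:.3f}")
    else:
        mtn_b_ids = ortho_mtn_b
    catalog_b = catalog_b.with_mtn_flags(mtn_b_ids)

    try:
        anchors = anchors_from_orthologs(omap_placed, catalog_a, catalog_b)
        blocks = chain_anchors(anchors, config.min_block_anchors, config.max_gap_genes)
        regions = merge_blocks(blocks, config.merge_distance)
        focal = focal_syntenic_regions(regions, config.focal_chrom_a, catalog_a)
    except Exception as exc:
        raise PipelineError("synteny", exc) from exc
    log.append(f"blocks {len(blocks)}, merged regions {len(regions)}, "
               f"focal regions {len(focal.regions)} "
               f"(coverage {focal.coverage:.3f})")

    try:
        table, obs = movement_table(
            omap_placed, regions, catalog_a, catalog_b, config.focal_chrom_a
        )
    except Exception as exc:
        raise PipelineError("movement", exc) from exc
    log.append(
        "movement observed "
        + " ".join(f"{c}={table.observed[c]}" for c in CATEGORIES)
        + f" retained={table.n_retained} p={table.p_value:.4f}"
    )

    try:
        biases = _abundance_stage(config, catalog_a, catalog_b, omap, focal, log)
        abundance_p = _abundance_fisher(biases)
    except Exception as exc:
        raise PipelineError("abundance", exc) from exc

    return RunResult(
        catalog_a, catalog_b, omap, omap_placed, regions, focal,
        table, obs, biases, abundance_p, mtn_overlap, log,
    )


def _abundance_stage(
    config: RunConfig,
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    omap: OrthologMap,
    focal: FocalSynteny,
    log: List[str],
) -> List[BiasResult]:
    """Bias of the focal chromosome, its syntenic counterpart, and each
    genome-A chromosome.

    In orthology mode, gene sets and totals are restricted to ortholog
    genes so the two genomes count the same loci; in annotation mode all
    annotated genes count.
    """
    if config.mtn_mode == "orthology":
        a_ids = {a for a, _ in omap.pairs}
        b_ids = {b for _, b in omap.pairs}
        genes_a = [g for g in catalog_a.genes if g.gene_id in a_ids]
        genes_b = [g for g in catalog_b.genes if g.gene_id in b_ids]
    else:
        genes_a = list(catalog_a.genes)
        genes_b = list(catalog_b.genes)
    total_a, total_mtn_a = len(genes_a), sum(g.is_mtn for g in genes_a)
    total_b, total_mtn_b = len(genes_b), sum(g.is_mtn for g in genes_b)
    results: List[BiasResult] = []

    def add(label: str, genes: List[Gene], total_mtn: int, total_genes: int) -> None:
        if not genes or total_mtn == 0:
            log.append(f"bias {label}: skipped (empty region or no class genes)")
            return
        results.append(region_bias(
            label, [g.is_mtn for g in genes], total_mtn, total_genes,
            config.n_boot, config.seed,
        ))

    focal_a_genes = [g for g in genes_a if g.chrom == config.focal_chrom_a]
    add("focal_A", focal_a_genes, total_mtn_a, total_a)
    in_focal_a = {g.gene_id for g in _genes_in_regions_a(catalog_a, focal.regions)}
    add("focal_A_syntenic", [g for g in genes_a if g.gene_id in in_focal_a],
        total_mtn_a, total_a)
    in_focal_b = {g.gene_id for g in _genes_in_regions_b(catalog_b, focal.regions)}
    add("focal_syntenic_B", [g for g in genes_b if g.gene_id in in_focal_b],
        total_mtn_b, total_b)
    for chrom in catalog_a.chroms:
        add(f"A:{chrom}", [g for g in genes_a if g.chrom == chrom],
            total_mtn_a, total_a)
    for r in results:
        log.append(
            f"bias {r.region_label}: {r.n_mtn}/{r.n_genes} genes, "
            f"bias {r.bias:.3f} [{r.ci_low:.3f}, {r.ci_high:.3f}]"
        )
    return results


def _abundance_fisher(biases: List[BiasResult]) -> Optional[float]:
    """2×2 exact test of the focal-A-syntenic vs focal-syntenic-B densities."""
    by_label = {b.region_label: b for b in biases}
    r1 = by_label.get("focal_A_syntenic")
    r2 = by_label.get("focal_syntenic_B")
    if r1 is None or r2 is None:
        return None
    return region_fisher(
        r1.n_mtn, round(r1.expected_mtn), r2.n_mtn, round(r2.expected_mtn)
    )


def write_report(result: RunResult, outdir: str, config: RunConfig) -> Dict[str, str]:
    """Write the TSV report bundle; on failure, remove partial outputs."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "regions": os.path.join(outdir, "regions.tsv"),
        "movement": os.path.join(outdir, "movement.tsv"),
        "bias": os.path.join(outdir, "bias.tsv"),
        "log": os.path.join(outdir, "run.log"),
    }
    written: List[str] = []
    try:
        with open(paths["regions"], "w") as fh:
            fh.write("chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\t"
                     "n_anchors\tn_blocks\tfocal\n")
            for r in result.regions:
                fh.write(
                    f"{r.chrom_a}\t{r.interval_a[0]}\t{r.interval_a[1]}\t"
                    f"{r.chrom_b}\t{r.interval_b[0]}\t{r.interval_b[1]}\t"
                    f"{r.n_anchors}\t{len(r.source_blocks)}\t"
                    f"{int(r.chrom_a == config.focal_chrom_a)}\n"
                )
        written.append(paths["regions"])
        with open(paths["movement"], "w") as fh:
            fh.write("category\tobserved\tobserved_no_ambiguous\texpected\n")
            no_amb = result.movement_obs.without_ambiguous()
            for c in CATEGORIES:
                fh.write(f"{c}\t{result.movement.observed[c]}\t{no_amb[c]}\t"
                         f"{result.movement.expected[c]:.3f}\n")
            fh.write(f"# retained\t{result.movement.n_retained}\n")
            fh.write(f"# p_value\t{result.movement.p_value:.6g}\n")
            fh.write(f"# expected_X>X_excluded\t{result.movement.x_to_x_expected:.3f}\n")
        written.append(paths["movement"])
        with open(paths["bias"], "w") as fh:
            fh.write("region\tn_mtn\tn_genes\texpected_mtn\tbias\tci_low\tci_high\n")
            for b in result.biases:
                fh.write(
                    f"{b.region_label}\t{b.n_mtn}\t{b.n_genes}\t"
                    f"{b.expected_mtn:.3f}\t{b.bias:.4f}\t"
                    f"{b.ci_low:.4f}\t{b.ci_high:.4f}\n"
                )
            if result.abundance_p is not None:
                fh.write(f"# abundance_fisher_p\t{result.abundance_p:.6g}\n")
        written.append(paths["bias"])
        with open(paths["log"], "w") as fh:
            for line in result.log_lines:
                fh.write(line + "\n")
        written.append(paths["log"])
    except Exception:
        for p in written:
            try:
                os.remove(p)
            except OSError:
                pass
        raise
    return paths
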