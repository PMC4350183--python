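"""Classify interchromosomal gene movement and test it against a size null.

An ortholog pair that falls inside a merged syntenic region (as an anchor,
or with both gene midpoints inside the region's corresponding intervals) is
*retained*; any other pair is a candidate movement. Movements are binned by
whether the source (genome B) lies in a focal-syntenic region and whether
the destination (genome A) is the focal chromosome: X→A, A→X, A→A.

Expected counts under the null redistribute the same number of movements in
proportion to the gene content of the source compartments and the physical
size (bp) of the target compartments. Observed and expected rows are then
compared with an exact 2×3 Freeman–Halton test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import GeneCatalog
from .orthology import OrthologMap
from .synteny import MergedRegion

CATEGORIES = ("X>A", "A>X", "A>A")


@dataclass
class MovementRecord:
    """One ortholog pair classified as a candidate movement."""

    pair: Tuple[str, str]
    chrom_a: str
    chrom_b: str
    category: str  # one of CATEGORIES or "X>X"
    ambiguous_origin: bool  # source chromosome only partly focal-syntenic


@dataclass
class MovementObservation:
    """Observed movement tallies for one genome pair."""

    observed: Dict[str, int]
    n_retained: int
    n_x_to_x: int
    records: List[MovementRecord] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.observed.values())

    def without_ambiguous(self) -> Dict[str, int]:
        """Sensitivity tally dropping movements from partly-syntenic sources."""
        out = {c: 0 for c in CATEGORIES}
        for r in self.records:
            if r.category in out and not r.ambiguous_origin:
                out[r.category] += 1
        return out


@dataclass
class MovementTable:
    """Observed vs expected movements plus the exact-test p-value."""

    observed: Dict[str, int]
    expected: Dict[str, float]
    n_retained: int
    p_value: float
    x_to_x_expected: float = 0.0


def classify_movements(
    omap: OrthologMap,
    merged_regions: Sequence[MergedRegion],
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    focal_chrom_a: str,
    class_filter: str = "mtn",
) -> MovementObservation:
    """Split ortholog pairs into retained vs moved and bin the movements.

    ``class_filter`` restricts the tally to mitonuclear pairs (flags on the
    genome-A gene); pass ``"all"`` to classify every pair. A movement's
    origin is ambiguous when its genome-B chromosome carries a
    focal-syntenic region but the gene itself sits outside it — such
    sources may be mis-assembled rather than truly non-syntenic.
    """
    focal_regions = [r for r in merged_regions if r.chrom_a == focal_chrom_a]
    focal_chroms_b = {r.chrom_b for r in focal_regions}
    anchored = {
        a.pair
        for r in merged_regions
        for blk in r.source_blocks
        for a in blk.anchors
    }
    observed = {c: 0 for c in CATEGORIES}
    records: List[MovementRecord] = []
    n_retained = 0
    n_xx = 0
    for a, b in omap.pairs:
        ga, gb = catalog_a[a], catalog_b[b]
        if class_filter == "mtn" and not ga.is_mtn:
            continue
        if (a, b) in anchored:
            n_retained += 1
            continue
        inside = any(
            r.contains_a(ga.midpoint, ga.chrom) and r.contains_b(gb.midpoint, gb.chrom)
            for r in merged_regions
        )
        if inside:
            n_retained += 1
            continue
        x_origin = any(r.contains_b(gb.midpoint, gb.chrom) for r in focal_regions)
        ambiguous = (not x_origin) and gb.chrom in focal_chroms_b
        x_dest = ga.chrom == focal_chrom_a
        if x_origin and x_dest:
            category = "X>X"
            n_xx += 1
        elif x_origin:
            category = "X>A"
        elif x_dest:
            category = "A>X"
        else:
            category = "A>A"
        if category in observed:
            observed[category] += 1
        records.append(MovementRecord((a, b), ga.chrom, gb.chrom, category, ambiguous))
    return MovementObservation(observed, n_retained, n_xx, records)


def expected_movements(
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    omap: OrthologMap,
    observed_total: int,
    focal_chrom_a: str,
    focal_regions: Sequence[MergedRegion],
    source_genes: str = "orthologs",
) -> Tuple[Dict[str, float], float]:
    """Expected movement counts under the size-and-content null.

    The chance a movement starts on the focal-syntenic compartment is the
    fraction of genome-B ortholog genes lying there (``source_genes="all"``
    uses every placed genome-B gene instead); the chance it lands on the
    focal chromosome is that chromosome's share of genome-A base pairs.
    The X→X mass is excluded from the three reported categories and the
    remainder rescaled so the expected row sums to ``observed_total``;
    the excluded mass is returned alongside.
    """
    if observed_total < 0:
        raise ValueError("observed_total must be >= 0")
    if observed_total == 0:
        return ({c: 0.0 for c in CATEGORIES}, 0.0)
    if source_genes == "orthologs":
        b_genes = [catalog_b[b] for _, b in omap.pairs if b in catalog_b]
    else:
        b_genes = [g for g in catalog_b.genes if g.placed]
    if not b_genes:
        raise ValueError("no genome-B genes available to estimate the source fraction")
    n_src = sum(
        any(r.contains_b(g.midpoint, g.chrom) for r in focal_regions) for g in b_genes
    )
    p_src = n_src / len(b_genes)
    p_tgt = catalog_a.chrom_lengths[focal_chrom_a] / catalog_a.total_bp
    t = float(observed_total)
    raw = {
        "X>A": t * p_src * (1.0 - p_tgt),
        "A>X": t * (1.0 - p_src) * p_tgt,
        "A>A": t * (1.0 - p_src) * (1.0 - p_tgt),
    }
    e_xx = t * p_src * p_tgt
    scale = t / (t - e_xx) if t > e_xx else 1.0
    return ({c: v * scale for c, v in raw.items()}, e_xx)


def fisher_exact_2x3(
    observed: Sequence[int], expected: Sequence[int]
) -> float:
    """Two-sided exact (Freeman–Halton) p for a 2×3 observed/expected table.

    Enumerates every 2×3 table with the observed margins and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the input. Computation is in exact integer arithmetic, so the
    "no more probable" comparison has no floating-point slack. Expected
    counts must already be rounded to integers (exact tests are defined on
    integer tables); rounding is deliberately the caller's step.
    """
    for row, name in ((observed, "observed"), (expected, "expected")):
        if len(row) != 3:
            raise ValueError(f"{name} row must have 3 entries")
        for v in row:
            if int(v) != v:
                raise ValueError(
                    f"{name} row contains non-integer {v!r}; round expected "
                    "counts to integers before testing"
                )
            if v < 0:
                raise ValueError(f"{name} row contains negative count {v!r}")
    obs = [int(v) for v in observed]
    exp = [int(v) for v in expected]
    r1, r2 = sum(obs), sum(exp)
    if r1 == 0 and r2 == 0:
        return 1.0
    cols = [obs[j] + exp[j] for j in range(3)]
    n = r1 + r2
    # weight(table) proportional to prod_j C(col_j, a_j); shared denominator
    w_obs = comb(cols[0], obs[0]) * comb(cols[1], obs[1]) * comb(cols[2], obs[2])
    total = 0
    extreme = 0
    for a0 in range(max(0, r1 - cols[1] - cols[2]), min(cols[0], r1) + 1):
        rem = r1 - a0
        w0 = comb(cols[0], a0)
        for a1 in range(max(0, rem - cols[2]), min(cols[1], rem) + 1):
            a2 = rem - a1
            w = w0 * comb(cols[1], a1) * comb(cols[2], a2)
            total += w
            if w <= w_obs:
                extreme += w
    return float(Fraction(extreme, total))


def movement_table(
    omap: OrthologMap,
    merged_regions: Sequence[MergedRegion],
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    focal_chrom_a: str,
    class_filter: str = "mtn",
    source_genes: str = "orthologs",
) -> Tuple[MovementTable, MovementObservation]:
    """End-to-end movement analysis for one genome pair.

    Classifies movements, computes the size-null expectation, rounds it to
    integers, and runs the exact 2×3 test. With zero observed movements the
    test is vacuous and p = 1.
    """
    obs = classify_movements(
        omap, merged_regions, catalog_a, catalog_b, focal_chrom_a, class_filter
    )
    focal_regions = [r for r in merged_regions if r.chrom_a == focal_chrom_a]
    expected, e_xx = expected_movements(
        catalog_a, catalog_b, omap, obs.total, focal_chrom_a, focal_regions,
        source_genes=source_genes,
    )
    if obs.total == 0:
        p = 1.0
    else:
        p = fisher_exact_2x3(
            [obs.observed[c] for c in CATEGORIES],
            [round(expected[c]) for c in CATEGORIES],
        )
    table = MovementTable(
        observed=dict(obs.observed),
        expected=expected,
        n_retained=obs.n_retained,
        p_value=p,
        x_to_x_expected=e_xx,
    )
    return table, obs
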