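"""Mitonuclear gene density ("bias") statistics for genomic regions.

For a region carrying ``n_genes`` of a genome's ``total_genes``, the
expected number of mitonuclear genes is the genome-wide total scaled by the
region's share of genes:

    expected = (n_genes / total_genes) * total_mtn
    bias     = n_mtn / expected

Bias below 1 means underrepresentation. Confidence intervals come from a
percentile bootstrap over the region's genes (genome totals held fixed);
regions are compared with a 2×2 exact test on observed vs expected counts,
and under/overrepresentation across independent lineages with an exact
two-tailed sign test.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats


@dataclass
class BiasResult:
    """Observed vs expected mitonuclear density in one region."""

    region_label: str
    n_mtn: int
    n_genes: int
    total_mtn: int
    total_genes: int
    expected_mtn: float
    bias: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    seed: Optional[int] = None


def bias(
    n_mtn: int, n_genes: int, total_mtn: int, total_genes: int
) -> Tuple[float, float]:
    """Return ``(expected_mtn, bias)`` for a region; pure arithmetic."""
    if n_genes <= 0:
        raise ValueError("bias is undefined for a region with no genes")
    if total_genes <= 0 or total_mtn <= 0:
        raise ValueError("genome totals must be positive")
    if not (0 <= n_mtn <= n_genes):
        raise ValueError("n_mtn must lie in [0, n_genes]")
    expected = (n_genes / total_genes) * total_mtn
    return expected, n_mtn / expected


def bootstrap_ci(
    region_gene_flags: Sequence[bool],
    total_mtn: int,
    total_genes: int,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for a region's bias.

    Each iteration resamples the region's genes with replacement and
    recomputes the bias with the genome totals fixed. Resampling a boolean
    flag vector with replacement is a binomial draw on the region's
    mitonuclear fraction, which is what is computed (vectorized);
    deterministic given ``seed``.
    """
    flags = np.asarray(region_gene_flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("cannot bootstrap an empty region")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if total_genes <= 0 or total_mtn <= 0:
        raise ValueError("genome totals must be positive")
    rng = np.random.default_rng(seed)
    expected = (n / total_genes) * total_mtn
    counts = rng.binomial(n, flags.mean(), size=n_boot)
    boot_bias = counts / expected
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot_bias, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def region_bias(
    region_label: str,
    region_gene_flags: Sequence[bool],
    total_mtn: int,
    total_genes: int,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> BiasResult:
    """Bias point estimate plus bootstrap CI for one region."""
    flags = np.asarray(region_gene_flags, dtype=bool)
    n_mtn = int(flags.sum())
    expected, b = bias(n_mtn, flags.size, total_mtn, total_genes)
    lo, hi = bootstrap_ci(flags, total_mtn, total_genes, n_boot, seed, level)
    return BiasResult(
        region_label, n_mtn, int(flags.size), total_mtn, total_genes,
        expected, b, lo, hi, n_boot, seed,
    )


def region_fisher(
    n_mtn_1: int, expected_1: int, n_mtn_2: int, expected_2: int
) -> float:
    """Two-tailed 2×2 exact test of observed vs expected counts in two regions.

    Expected counts must be pre-rounded to integers. A table of all zeros
    is vacuous: p = 1.
    """
    for v in (n_mtn_1, expected_1, n_mtn_2, expected_2):
        if int(v) != v or v < 0:
            raise ValueError("counts must be non-negative integers (round expected first)")
    table = [[int(n_mtn_1), int(expected_1)], [int(n_mtn_2), int(expected_2)]]
    if sum(table[0]) + sum(table[1]) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def sign_test(n_under: int, n_total: int) -> float:
    """Exact two-tailed sign test: 2·min(tail probabilities), capped at 1.

    ``n_under`` of ``n_total`` independent lineages show the deficit; under
    the null each direction is a fair coin.
    """
    if n_total <= 0:
        raise ValueError("sign test needs at least one observation")
    if not (0 <= n_under <= n_total):
        raise ValueError("n_under must lie in [0, n_total]")
    k, n = n_under, n_total
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def flag_overlap(flags_1: Iterable[str], flags_2: Iterable[str]) -> float:
    """Jaccard overlap between two mitonuclear gene-id sets.

    Used to compare annotation-derived vs orthology-derived flags; returns
    1.0 when both sets are empty.
    """
    s1, s2 = set(flags_1), set(flags_2)
    union = s1 | s2
    if not union:
        return 1.0
    return len(s1 & s2) / len(union)
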