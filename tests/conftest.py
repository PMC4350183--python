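import io

import pytest

from synmito import GeneCatalog, Gene, SimConfig, simulate
from synmito.synteny import SyntenyAnchor


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulation shared across tests (seed 42)."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def sim_quiet():
    """Rearrangement-only evolution: no single-gene movement, no hit noise."""
    return simulate(SimConfig(seed=11, move_rate=0.0, paralog_rate=0.0,
                              n_inversions=4, n_translocations=1))


def make_catalog(label, layout, chrom_len=1_000_000):
    """Tiny catalog from {chrom: [(gene_id, start, end, is_mtn), ...]}."""
    genes = []
    lengths = {}
    for chrom, rows in layout.items():
        lengths[chrom] = chrom_len
        for row in rows:
            gid, start, end = row[:3]
            is_mtn = row[3] if len(row) > 3 else False
            genes.append(Gene(gid, chrom, start, end, is_mtn=is_mtn))
    return GeneCatalog(label, genes, lengths)


def make_anchors(pairs, chrom_a="cA", chrom_b="cB", spacing=100_000):
    """Anchors from (rank_a, rank_b) tuples, evenly spaced coordinates."""
    return [
        SyntenyAnchor(
            pair=(f"a{ra}", f"b{rb}"), chrom_a=chrom_a, chrom_b=chrom_b,
            rank_a=ra, rank_b=rb,
            span_a=(ra * spacing, ra * spacing + 1000),
            span_b=(rb * spacing, rb * spacing + 1000),
        )
        for ra, rb in pairs
    ]


def text(s):
    return io.StringIO(s)
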