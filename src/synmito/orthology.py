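"""One-to-one ortholog inference by reciprocal best BLAST hit (rBBH).

A pair (a, b) is an ortholog pair when b is a's top-scoring hit in the
A→B search and a is b's top-scoring hit in the B→A search. Hits are first
screened on e-value (default < 1e-10); the 30% sequence-identity rule is
applied to the top hit only — a query whose best hit is too diverged yields
no ortholog rather than falling back to a worse hit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .model import GeneCatalog, HomologyHit

DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_MIN_IDENTITY = 30.0


@dataclass
class OrthologMap:
    """A one-to-one, symmetric gene pairing between two genomes.

    ``provenance`` keeps the best hit in each direction for every pair,
    keyed by the (gene_a, gene_b) tuple.
    """

    pairs: List[Tuple[str, str]] = field(default_factory=list)
    provenance: Dict[Tuple[str, str], Dict[str, HomologyHit]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return pair in set(self.pairs)

    @property
    def a_to_b(self) -> Dict[str, str]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> Dict[str, str]:
        return {b: a for a, b in self.pairs}


def filter_hits(
    hits: Iterable[HomologyHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    strict: bool = False,
) -> List[HomologyHit]:
    """Screen hits on e-value (strict ``<``); identity only if ``strict``.

    By default the identity threshold is *not* applied here: it belongs to
    the top hit (see :func:`best_hit`), so a low-identity best hit vetoes the
    query instead of promoting the runner-up. ``strict=True`` additionally
    drops every hit at or below ``min_identity``.
    """
    out = [h for h in hits if h.evalue < max_evalue]
    if strict:
        out = [h for h in out if h.pct_identity > min_identity]
    return out


def _hit_sort_key(h: HomologyHit) -> tuple:
    # bitscore desc, evalue asc, identity desc, subject id asc
    return (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id)


def best_hit(
    hits_for_one_query: Iterable[HomologyHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Optional[HomologyHit]:
    """Top hit of one query by (bitscore, e-value, identity, subject id).

    Returns ``None`` for an empty hit list or when the top hit's identity is
    not above ``min_identity`` — the query then has no usable best hit at
    all, by design.
    """
    hits = sorted(hits_for_one_query, key=_hit_sort_key)
    if not hits:
        return None
    top = hits[0]
    if top.pct_identity <= min_identity:
        return None
    return top


def _best_hits_by_query(
    hits: Iterable[HomologyHit], min_identity: float
) -> Dict[str, HomologyHit]:
    grouped: Dict[str, List[HomologyHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    out: Dict[str, HomologyHit] = {}
    for qid, qhits in grouped.items():
        top = best_hit(qhits, min_identity)
        if top is not None:
            out[qid] = top
    return out


def reciprocal_best_hits(
    hits_a_to_b: Iterable[HomologyHit],
    hits_b_to_a: Iterable[HomologyHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    prefiltered: bool = False,
) -> OrthologMap:
    """Infer one-to-one orthologs by mutual best hit.

    Both hit tables are e-value filtered unless ``prefiltered``. The result
    is one-to-one by construction: each gene has at most one best hit, and a
    pair requires agreement in both directions.
    """
    if not prefiltered:
        hits_a_to_b = filter_hits(hits_a_to_b, max_evalue)
        hits_b_to_a = filter_hits(hits_b_to_a, max_evalue)
    best_ab = _best_hits_by_query(hits_a_to_b, min_identity)
    best_ba = _best_hits_by_query(hits_b_to_a, min_identity)
    pairs: List[Tuple[str, str]] = []
    provenance: Dict[Tuple[str, str], Dict[str, HomologyHit]] = {}
    for a in sorted(best_ab):
        fwd = best_ab[a]
        b = fwd.subject_id
        rev = best_ba.get(b)
        if rev is not None and rev.subject_id == a:
            pairs.append((a, b))
            provenance[(a, b)] = {"a_to_b": fwd, "b_to_a": rev}
    return OrthologMap(pairs, provenance)


def restrict_to_placed(
    omap: OrthologMap, catalog_a: GeneCatalog, catalog_b: GeneCatalog
) -> OrthologMap:
    """Keep pairs where both genes sit on sequences usable for synteny.

    Pairs whose genes are missing from a catalog are dropped as unplaced.
    """
    pairs: List[Tuple[str, str]] = []
    provenance = {}
    for a, b in omap.pairs:
        ga, gb = catalog_a.get(a), catalog_b.get(b)
        if ga is not None and gb is not None and ga.placed and gb.placed:
            pairs.append((a, b))
            if (a, b) in omap.provenance:
                provenance[(a, b)] = omap.provenance[(a, b)]
    return OrthologMap(pairs, provenance)
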