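"""Readers and writers for the external formats the pipeline touches.

Formats: BED6 and GFF3 gene tables, two-column chromosome-length TSV,
BLAST tabular output (``-outfmt 6``, 12 columns), gene→GO annotation TSV,
and the MCScanX ``.collinearity`` dialect. Coordinates are converted to the
internal 0-based half-open convention on read and back on write.
"""
from __future__ import annotations

import io as _io
import re
from typing import Dict, Iterable, List, Optional, Set, TextIO, Tuple, Union

import pandas as pd

from .model import Gene, GeneCatalog, HomologyHit

Stream = Union[str, TextIO]

MITO_GO_TERM = "GO:0005739"

_GFF3_ID_RX = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def _open(stream: Stream, mode: str = "r"):
    if isinstance(stream, str):
        return open(stream, mode), True
    return stream, False


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def read_chrom_lengths(stream: Stream) -> Dict[str, int]:
    """Two-column TSV ``chrom<TAB>length_bp``."""
    fh, close = _open(stream)
    try:
        lengths: Dict[str, int] = {}
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(lineno, f"expected 2 columns, got {len(parts)}")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise ParseError(lineno, f"non-integer length {parts[1]!r}") from None
        return lengths
    finally:
        if close:
            fh.close()


def write_chrom_lengths(lengths: Dict[str, int], stream: Stream) -> None:
    fh, close = _open(stream, "w")
    try:
        for chrom in sorted(lengths):
            fh.write(f"{chrom}\t{lengths[chrom]}\n")
    finally:
        if close:
            fh.close()


def _parse_bed_line(lineno: int, line: str) -> Gene:
    parts = line.split("\t")
    if len(parts) < 4:
        raise ParseError(lineno, f"BED line needs >= 4 columns, got {len(parts)}")
    chrom, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
    strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}") from None
    try:
        return Gene(name, chrom, start, end, strand)
    except ValueError as exc:
        raise ParseError(lineno, str(exc)) from None


def _parse_gff3_line(lineno: int, line: str) -> Optional[Gene]:
    parts = line.split("\t")
    if len(parts) != 9:
        raise ParseError(lineno, f"GFF3 line needs 9 columns, got {len(parts)}")
    chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
    if ftype != "gene":
        return None
    m = _GFF3_ID_RX.search(attrs)
    if m is None:
        raise ParseError(lineno, "gene feature without ID attribute")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}") from None
    if strand not in ("+", "-"):
        strand = "."
    try:
        # GFF3 is 1-based closed: [start, end] -> internal [start-1, end)
        return Gene(m.group(1), chrom, start - 1, end, strand)
    except ValueError as exc:
        raise ParseError(lineno, str(exc)) from None


def read_gene_table(
    stream: Stream,
    fmt: str,
    chrom_lengths: Union[Stream, Dict[str, int]],
    genome_label: str = "genome",
) -> GeneCatalog:
    """Read a BED or GFF3 gene table into a :class:`GeneCatalog`.

    Genes on chromosomes absent from the lengths table are rejected with an
    error naming the gene; duplicate gene ids are rejected likewise.
    """
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown gene-table format {fmt!r}")
    if not isinstance(chrom_lengths, dict):
        chrom_lengths = read_chrom_lengths(chrom_lengths)
    fh, close = _open(stream)
    try:
        genes: List[Gene] = []
        seen: Set[str] = set()
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if fmt == "BED":
                gene = _parse_bed_line(lineno, line)
            else:
                gene = _parse_gff3_line(lineno, line)
                if gene is None:
                    continue
            if gene.gene_id in seen:
                raise ParseError(lineno, f"duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
        return GeneCatalog(genome_label, genes, chrom_lengths)
    finally:
        if close:
            fh.close()


def write_gene_table(catalog: GeneCatalog, stream: Stream, fmt: str = "BED") -> None:
    """Write a catalog back out as BED6 or GFF3 (genes in catalog order)."""
    fh, close = _open(stream, "w")
    try:
        for g in catalog.genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            if fmt == "BED":
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")
            elif fmt == "GFF3":
                s = strand if strand != "." else "."
                fh.write(
                    f"{g.chrom}\tsynmito\tgene\t{g.start + 1}\t{g.end}\t.\t{s}\t.\t"
                    f"ID={g.gene_id}\n"
                )
            else:
                raise ValueError(f"unknown gene-table format {fmt!r}")
    finally:
        if close:
            fh.close()


_OUTFMT6_COLS = [
    "query_id", "subject_id", "pct_identity", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(stream: Stream) -> List[HomologyHit]:
    """Read 12-column BLAST tabular output; row order is preserved.

    Only query, subject, identity, evalue and bitscore are kept — the
    alignment-coordinate columns play no role downstream.
    """
    fh, close = _open(stream)
    try:
        df = pd.read_csv(
            fh, sep="\t", header=None, comment="#",
            dtype={0: str, 1: str}, float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return []
    finally:
        if close:
            fh.close()
    if df.shape[1] != 12:
        raise ValueError(
            f"expected 12 tab-separated columns (BLAST -outfmt 6), got {df.shape[1]}"
        )
    df.columns = _OUTFMT6_COLS
    for col in ("pct_identity", "evalue", "bitscore"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0] + 1
            raise ParseError(int(bad), f"non-numeric {col}")
    return [
        HomologyHit(r.query_id, r.subject_id, float(r.pct_identity),
                    float(r.evalue), float(r.bitscore))
        for r in df.itertuples(index=False)
    ]


def write_hit_table(hits: Iterable[HomologyHit], stream: Stream) -> None:
    """Write hits as 12-column BLAST tabular rows (unused columns zeroed)."""
    fh, close = _open(stream, "w")
    try:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t0\t0\t0\t"
                f"0\t0\t0\t0\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )
    finally:
        if close:
            fh.close()


def read_go_annotations(stream: Stream, mito_term: str = MITO_GO_TERM) -> Set[str]:
    """Return the gene ids annotated with ``mito_term`` in a two-column TSV."""
    fh, close = _open(stream)
    try:
        out: Set[str] = set()
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(lineno, f"expected 2 columns, got {len(parts)}")
            if parts[1] == mito_term:
                out.add(parts[0])
        return out
    finally:
        if close:
            fh.close()


def write_go_annotations(
    gene_ids: Iterable[str], stream: Stream, term: str = MITO_GO_TERM
) -> None:
    fh, close = _open(stream, "w")
    try:
        for gid in sorted(set(gene_ids)):
            fh.write(f"{gid}\t{term}\n")
    finally:
        if close:
            fh.close()


_ALIGN_HDR_RX = re.compile(
    r"^##\s*Alignment\s+(\d+):\s*score=\S+\s+e_value=\S+\s+N=(\d+)\s+"
    r"(\S+)&(\S+)\s+(plus|minus)"
)


def read_collinearity(stream: Stream):
    """Parse the MCScanX ``.collinearity`` text dialect into raw block records.

    Returns a list of ``(chrom_a, chrom_b, orientation, anchor_pairs)``
    tuples, where orientation is ``"same"`` (plus) or ``"inverted"`` (minus)
    and anchor_pairs is an ordered list of ``(gene_id_a, gene_id_b)``.
    Conversion into scored synteny blocks (with ranks and spans) happens in
    :func:`synmito.synteny.blocks_from_collinearity`, which needs catalogs.
    """
    fh, close = _open(stream)
    try:
        records = []
        current = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("## Alignment") or line.startswith("##Alignment"):
                m = _ALIGN_HDR_RX.match(line)
                if m is None:
                    raise ParseError(lineno, f"malformed alignment header: {line!r}")
                orientation = "same" if m.group(5) == "plus" else "inverted"
                current = (m.group(3), m.group(4), orientation, [])
                records.append(current)
            elif line.startswith("#") or not line.strip():
                continue
            else:
                if current is None:
                    raise ParseError(lineno, "anchor row before any alignment header")
                # "  0-  0:\tgeneA\tgeneB\t  1e-50"
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(lineno, f"anchor row needs >= 3 fields, got {len(fields)}")
                current[3].append((fields[1].strip(), fields[2].strip()))
        return records
    finally:
        if close:
            fh.close()


def write_collinearity(blocks, stream: Stream) -> None:
    """Write synteny blocks in the MCScanX ``.collinearity`` dialect."""
    fh, close = _open(stream, "w")
    try:
        fh.write("############### Parameters ###############\n")
        for i, b in enumerate(blocks):
            word = "plus" if b.orientation == "same" else "minus"
            fh.write(
                f"## Alignment {i}: score={len(b.anchors) * 50:.1f} e_value=0 "
                f"N={len(b.anchors)} {b.chrom_a}&{b.chrom_b} {word}\n"
            )
            for j, a in enumerate(b.anchors):
                fh.write(f"{i:3d}-{j:3d}:\t{a.pair[0]}\t{a.pair[1]}\t      0\n")
    finally:
        if close:
            fh.close()
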