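"""Readers and writers for the external text formats.

Supported formats: Ensembl-dialect GTF, SAM v1 text, TSV count tables
(HTSeq-style special rows), GMT annotation sets, plain-text ID lists and
a three-column TSV edge list importable into BioLayout or Cytoscape.
"""

from __future__ import annotations

import io as _io
import logging
import re
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .counting import AlignedRead
from .models import (
    SPECIAL_COUNTERS,
    CountTable,
    GeneModel,
    GenomicInterval,
    ParseError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

TextSource = Union[str, PathLike, IO[str], Iterable[str]]

_INTRON_PREFIX = "__intron_"


def _as_lines(source: TextSource) -> Iterator[str]:
    """Accept a path, an open text handle, an iterable of lines, or a literal
    multi-line string (distinguished from a path by containing a newline)."""
    if isinstance(source, (str, PathLike)):
        if isinstance(source, str) and ("\n" in source or "\t" in source or not source):
            yield from _io.StringIO(source)
            return
        with open(source, "rt") as fh:
            yield from fh
        return
    yield from source


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if attrs:
        return attrs
    # tolerate unquoted `key value;` dialects
    out = {}
    for chunk in attr_field.strip().strip(";").split(";"):
        parts = chunk.strip().split(None, 1)
        if len(parts) == 2:
            out[parts[0]] = parts[1].strip().strip('"')
    return out


def parse_gtf(
    source: TextSource, level: str = "gene"
) -> Union[list[GeneModel], list[TranscriptModel]]:
    """Parse exon lines of a GTF into gene or transcript models.

    GTF coordinates are 1-based inclusive; models use 0-based half-open.
    One model is produced per distinct gene_id (``level='gene'``) or
    transcript_id (``level='transcript'``), in order of first appearance.
    """
    if level not in ("gene", "transcript"):
        raise ValueError(f"unknown level {level!r}")

    # transcript_id -> (gene_id, biotype, exon list); insertion-ordered
    tx_exons: dict[str, dict] = {}
    gene_meta: dict[str, dict] = {}

    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(
                f"expected 9 tab-separated columns, got {len(fields)}", lineno
            )
        chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
        if feature != "exon":
            continue
        attrs = _parse_attributes(attr)
        gene_id = attrs.get("gene_id")
        transcript_id = attrs.get("transcript_id")
        if not gene_id:
            raise ParseError("exon line lacks gene_id attribute", lineno)
        if not transcript_id:
            raise ParseError("exon line lacks transcript_id attribute", lineno)
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise ParseError(f"non-integer coordinates {start!r}/{end!r}", lineno)
        iv = GenomicInterval(chrom, start_i - 1, end_i, strand if strand in "+-" else ".")
        biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
        rec = tx_exons.setdefault(
            transcript_id,
            {
                "gene_id": gene_id,
                "biotype": attrs.get("transcript_biotype", biotype),
                "exons": [],
            },
        )
        rec["exons"].append(iv)
        gene_meta.setdefault(
            gene_id, {"name": attrs.get("gene_name", ""), "biotype": biotype}
        )

    transcripts = [
        TranscriptModel(tid, rec["gene_id"], rec["biotype"], rec["exons"])
        for tid, rec in tx_exons.items()
    ]
    if level == "transcript":
        return transcripts

    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [
        GeneModel(
            gene_id=gid,
            gene_name=gene_meta[gid]["name"],
            biotype=gene_meta[gid]["biotype"],
            transcripts=txs,
        )
        for gid, txs in by_gene.items()
    ]


def write_gtf(models: Sequence[Union[GeneModel, TranscriptModel]]) -> str:
    """Emit exon lines (1-based inclusive coordinates) for the given models."""
    lines = []
    transcripts: list[TranscriptModel] = []
    for m in models:
        if isinstance(m, GeneModel):
            transcripts.extend(m.transcripts)
        else:
            transcripts.append(m)
    for t in transcripts:
        for e in t.exons:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.biotype:
                attrs += f' gene_biotype "{t.biotype}";'
            lines.append(
                "\t".join(
                    [
                        e.chrom,
                        "coexmap",
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        e.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# SAM

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def cigar_blocks(pos0: int, cigar: str, chrom: str, strand: str = ".") -> list[GenomicInterval]:
    """Reference-consuming blocks of a CIGAR starting at 0-based ``pos0``.

    M/=/X and D extend the current block; N closes it and opens a new one
    after the gap; I/S/H/P consume no reference.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or sum(int(n) for n, _ in ops) == 0:
        raise ValueError(f"invalid CIGAR {cigar!r}")
    if _CIGAR_RE.sub("", cigar):
        raise ValueError(f"invalid CIGAR {cigar!r}")
    blocks: list[GenomicInterval] = []
    ref = pos0
    block_start = None
    for n_str, op in ops:
        n = int(n_str)
        if op in "M=XD":
            if block_start is None:
                block_start = ref
            ref += n
        elif op == "N":
            if block_start is not None and ref > block_start:
                blocks.append(GenomicInterval(chrom, block_start, ref, strand))
            block_start = None
            ref += n
        # I, S, H, P: no reference consumed
    if block_start is not None and ref > block_start:
        blocks.append(GenomicInterval(chrom, block_start, ref, strand))
    if not blocks:
        raise ValueError(f"CIGAR {cigar!r} consumes no reference")
    return blocks


class SamReader:
    """Iterate mapped primary alignments of a SAM text source.

    Unmapped, secondary and supplementary records are skipped and
    tallied; records with an invalid CIGAR are counted in ``n_bad_cigar``
    and logged, and processing continues.
    """

    def __init__(self, source: TextSource):
        self._source = source
        self.n_unmapped = 0
        self.n_secondary = 0
        self.n_supplementary = 0
        self.n_bad_cigar = 0

    def __iter__(self) -> Iterator[AlignedRead]:
        for lineno, raw in enumerate(_as_lines(self._source), start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(
                    f"SAM record has {len(fields)} fields (need >= 11)", lineno
                )
            qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
            try:
                flag = int(flag_s)
            except ValueError:
                raise ParseError(f"non-integer FLAG {flag_s!r}", lineno)
            if flag & FLAG_UNMAPPED or rname == "*":
                self.n_unmapped += 1
                continue
            if flag & FLAG_SECONDARY:
                self.n_secondary += 1
                continue
            if flag & FLAG_SUPPLEMENTARY:
                self.n_supplementary += 1
                continue
            n_hits = 1
            for tag in fields[11:]:
                if tag.startswith("NH:i:"):
                    n_hits = int(tag[5:])
                    break
            strand = "-" if flag & 0x10 else "+"
            try:
                blocks = cigar_blocks(int(pos_s) - 1, cigar, rname, strand)
            except ValueError as exc:
                self.n_bad_cigar += 1
                logger.warning("skipping record %s at line %d: %s", qname, lineno, exc)
                continue
            yield AlignedRead(
                read_id=qname,
                chrom=rname,
                blocks=blocks,
                mapq=int(mapq_s),
                n_hits=n_hits,
            )


def parse_sam(source: TextSource) -> SamReader:
    """Convenience constructor for :class:`SamReader`."""
    return SamReader(source)


# ---------------------------------------------------------------------------
# Count tables

def write_count_table(table: CountTable) -> str:
    """Serialize to TSV: feature rows, then __intron_<gene> rows, then the
    HTSeq-style __ special rows."""
    out = ["feature_id\t" + "\t".join(table.sample_ids)]
    for i, fid in enumerate(table.feature_ids):
        out.append(fid + "\t" + "\t".join(str(c) for c in table.counts[i]))
    if table.intron_counts is not None:
        for i, gid in enumerate(table.intron_gene_ids):
            out.append(
                f"{_INTRON_PREFIX}{gid}\t"
                + "\t".join(str(c) for c in table.intron_counts[i])
            )
    for name in SPECIAL_COUNTERS:
        if name in table.special_counts:
            out.append(
                f"__{name}\t" + "\t".join(str(c) for c in table.special_counts[name])
            )
    return "\n".join(out) + "\n"


def read_count_table(source: TextSource) -> CountTable:
    """Parse the TSV produced by :func:`write_count_table`."""
    lines = [ln.rstrip("\n") for ln in _as_lines(source)]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ParseError("empty count table")
    header = lines[0].split("\t")
    if header[0] != "feature_id":
        raise ParseError("first header column must be 'feature_id'", 1)
    sample_ids = header[1:]
    n = len(sample_ids)
    feature_ids: list[str] = []
    rows: list[list[int]] = []
    intron_ids: list[str] = []
    intron_rows: list[list[int]] = []
    special: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise ParseError(
                f"expected {n + 1} columns, got {len(fields)}", lineno
            )
        fid, cells = fields[0], fields[1:]
        try:
            values = [int(c) for c in cells]
        except ValueError:
            bad = next(c for c in cells if not c.lstrip("-").isdigit())
            raise ParseError(f"non-integer cell {bad!r} in row {fid!r}", lineno)
        if fid.startswith(_INTRON_PREFIX):
            intron_ids.append(fid[len(_INTRON_PREFIX):])
            intron_rows.append(values)
        elif fid.startswith("__"):
            name = fid[2:]
            if name not in SPECIAL_COUNTERS:
                raise ParseError(f"unknown special row {fid!r}", lineno)
            special[name] = np.array(values, dtype=np.int64)
        else:
            feature_ids.append(fid)
            rows.append(values)
    return CountTable(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        counts=np.array(rows, dtype=np.int64).reshape(len(feature_ids), n),
        intron_gene_ids=intron_ids,
        intron_counts=(
            np.array(intron_rows, dtype=np.int64).reshape(len(intron_ids), n)
            if intron_ids
            else None
        ),
        special_counts=special,
    )


# ---------------------------------------------------------------------------
# GMT / ID lists

def read_gmt(source: TextSource) -> dict[str, set[str]]:
    """GMT: term <tab> description <tab> member1 <tab> member2 ..."""
    terms: dict[str, set[str]] = {}
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("GMT line needs at least term and description", lineno)
        term = fields[0]
        if term in terms:
            raise ParseError(f"duplicate term {term!r}", lineno)
        terms[term] = {m for m in fields[2:] if m}
    return terms


def read_id_list(source: TextSource) -> list[str]:
    """Plain-text ID list, one per line; blanks and #-comments ignored."""
    ids = []
    for raw in _as_lines(source):
        s = raw.strip()
        if s and not s.startswith("#"):
            ids.append(s)
    return ids


# ---------------------------------------------------------------------------
# Edge list export

def write_edge_list(cmap, k: Union[int, float]) -> str:
    """Top-k neighborhood union as a three-column TSV (idA, idB, r).

    ``k`` may be an integer neighbor count or a fraction of the map size.
    Each undirected pair appears once with idA < idB; no self-edges.
    """
    n = len(cmap.feature_ids)
    if isinstance(k, float) and 0 < k < 1:
        k = max(1, int(np.ceil(k * n)))
    k = int(k)
    if k <= 0:
        raise ValueError("k must be positive")
    edges: dict[tuple[str, str], float] = {}
    for fid in cmap.feature_ids:
        for entry in cmap.neighbors(fid, k):
            a, b = sorted((fid, entry.neighbor_id))
            edges[(a, b)] = entry.r
    lines = ["\t".join([a, b, format(r, ".6g")]) for (a, b), r in sorted(edges.items())]
    return "\n".join(lines) + ("\n" if lines else "")
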