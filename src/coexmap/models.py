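"""Core domain types: genomic intervals, gene/transcript models, count tables.

All internal coordinates are 0-based half-open.  GTF (1-based inclusive)
and SAM POS (1-based) are converted at the parse boundary and converted
back on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: Names of the per-sample special counters, in output order.
SPECIAL_COUNTERS = ("no_feature", "ambiguous", "not_unique", "low_quality")


class CoexmapError(Exception):
    """Base class for data errors raised by this package."""


class ParseError(CoexmapError):
    """A malformed record in an input file; carries a line number when known."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or adjacent intervals into a disjoint sorted union."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def complement_within(
    span: GenomicInterval, blocks: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intervals of ``span`` not covered by ``blocks`` (blocks disjoint, sorted)."""
    out: list[GenomicInterval] = []
    cursor = span.start
    for b in blocks:
        if b.start > cursor:
            out.append(GenomicInterval(span.chrom, cursor, b.start, span.strand))
        cursor = max(cursor, b.end)
    if cursor < span.end:
        out.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
    return out


@dataclass
class TranscriptModel:
    """One transcript: an ordered set of disjoint exons on one chromosome."""

    transcript_id: str
    gene_id: str
    biotype: str = ""
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = merge_intervals(self.exons)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class GeneModel:
    """A gene with its transcripts; exonic union and intronic region derived."""

    gene_id: str
    gene_name: str = ""
    biotype: str = ""
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @cached_property
    def exonic_union(self) -> list[GenomicInterval]:
        return merge_intervals(e for t in self.transcripts for e in t.exons)

    @cached_property
    def span(self) -> GenomicInterval:
        u = self.exonic_union
        return GenomicInterval(self.chrom, u[0].start, u[-1].end, self.strand)

    @cached_property
    def intronic_region(self) -> list[GenomicInterval]:
        return complement_within(self.span, self.exonic_union)


@dataclass
class CountTable:
    """Integer feature x sample counts plus intron rows and special counters.

    ``counts`` holds only genuine feature rows; intron counts and the
    special counters (no_feature, ambiguous, not_unique, low_quality) are
    kept separately so that downstream normalization can exclude them
    without string matching.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    intron_gene_ids: list[str] = field(default_factory=list)
    intron_counts: Optional[np.ndarray] = None
    special_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if self.intron_counts is not None:
            self.intron_counts = np.asarray(self.intron_counts, dtype=np.int64)
            if self.intron_counts.shape != (
                len(self.intron_gene_ids),
                len(self.sample_ids),
            ):
                raise ValueError("intron_counts shape mismatch")
        for name, vec in self.special_counts.items():
            if name not in SPECIAL_COUNTERS:
                raise ValueError(f"unknown special counter {name!r}")
            self.special_counts[name] = np.asarray(vec, dtype=np.int64)
            if self.special_counts[name].shape != (len(self.sample_ids),):
                raise ValueError(f"special counter {name!r} length mismatch")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None


@dataclass
class ExpressionMatrix:
    """Per-sample expression fractions (each column sums to 1 before filtering)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match label lists")
        if (self.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset, preserving the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in feature_ids]
        return ExpressionMatrix(
            list(feature_ids), list(self.sample_ids), self.values[rows, :]
        )
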