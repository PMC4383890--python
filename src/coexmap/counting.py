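"""Read-to-feature assignment with overlap-size disambiguation.

Reads are assigned to genes (or transcripts) by the number of aligned
reference bases falling inside each candidate's exonic region.  The
feature with the strictly largest exonic overlap wins; exact ties are
ambiguous, never broken by feature ID.  Reads with exonic overlap zero
but positive intronic overlap are counted as intronic for the gene with
the largest intronic overlap.  A compatibility mode reproduces
HTSeq-count union-mode semantics, where overlap size is ignored and any
read touching the exons of two or more genes is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree

from .models import (
    SPECIAL_COUNTERS,
    CountTable,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)

logger = logging.getLogger(__name__)


@dataclass
class AlignedRead:
    """A mapped primary alignment reduced to its reference-consuming blocks.

    ``blocks`` are the M/=/X/D runs of the CIGAR string as half-open
    intervals; N gaps split blocks.  Insertions and clips consume no
    reference and do not appear.
    """

    read_id: str
    chrom: str
    blocks: list[GenomicInterval]
    mapq: int = 255
    n_hits: int = 1

    def __post_init__(self):
        if not self.blocks:
            raise ValueError(f"read {self.read_id} has no aligned blocks")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"read {self.read_id} blocks out of order")

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0].start, self.blocks[-1].end


@dataclass
class Assignment:
    category: str  # feature | intron | ambiguous | no_feature | not_unique | low_quality
    feature_id: Optional[str] = None
    overlap_bases: int = 0

    def __post_init__(self):
        in_feature = self.category in ("feature", "intron")
        if in_feature != (self.feature_id is not None):
            raise ValueError(
                f"feature_id must be set iff category is feature/intron "
                f"(got {self.category}, {self.feature_id})"
            )


@dataclass
class CounterConfig:
    mode: str = "max_overlap"  # or "htseq_union"
    level: str = "gene"  # or "transcript"
    transcript_ambiguous_multicount: bool = False
    min_mapq: int = 0
    count_introns: bool = True

    def __post_init__(self):
        if self.mode not in ("max_overlap", "htseq_union"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.level not in ("gene", "transcript"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.transcript_ambiguous_multicount and self.level != "transcript":
            raise ValueError("multicount applies only at transcript level")


def overlap_bases(
    read: AlignedRead, region: Sequence[GenomicInterval]
) -> int:
    """Aligned reference bases of ``read`` falling inside ``region``.

    Sum of block x interval intersections; both sides are disjoint sorted
    interval lists, so a merge scan suffices.
    """
    total = 0
    for b in read.blocks:
        for iv in region:
            if iv.chrom != b.chrom:
                continue
            lo = max(b.start, iv.start)
            hi = min(b.end, iv.end)
            if hi > lo:
                total += hi - lo
    return total


Feature = Union[GeneModel, TranscriptModel]


def _exonic(feature: Feature) -> Sequence[GenomicInterval]:
    if isinstance(feature, GeneModel):
        return feature.exonic_union
    return feature.exons


def _feature_id(feature: Feature) -> str:
    if isinstance(feature, GeneModel):
        return feature.gene_id
    return feature.transcript_id


def assign_read(
    read: AlignedRead,
    candidates: Sequence[Feature],
    cfg: CounterConfig,
) -> Assignment:
    """Assign one read to a category under the configured mode.

    ``candidates`` must be every feature whose span intersects any read
    block; an empty list yields ``no_feature``.
    """
    if read.n_hits > 1:
        return Assignment("not_unique")
    if read.mapq < cfg.min_mapq:
        return Assignment("low_quality")

    exonic = [(f, overlap_bases(read, _exonic(f))) for f in candidates]
    hits = [(f, ov) for f, ov in exonic if ov > 0]

    if cfg.mode == "htseq_union":
        # Union mode: overlap size is ignored; >=2 overlapped features is
        # ambiguous and introns are not features.
        if len(hits) == 1:
            f, ov = hits[0]
            return Assignment("feature", _feature_id(f), ov)
        if len(hits) >= 2:
            return Assignment("ambiguous")
        return Assignment("no_feature")

    # max_overlap mode
    if hits:
        best = max(ov for _, ov in hits)
        winners = [f for f, ov in hits if ov == best]
        if len(winners) == 1:
            return Assignment("feature", _feature_id(winners[0]), best)
        return Assignment("ambiguous")

    if cfg.count_introns and cfg.level == "gene":
        intronic = [
            (f, overlap_bases(read, f.intronic_region))
            for f in candidates
            if isinstance(f, GeneModel)
        ]
        ihits = [(f, ov) for f, ov in intronic if ov > 0]
        if ihits:
            best = max(ov for _, ov in ihits)
            winners = [f for f, ov in ihits if ov == best]
            if len(winners) == 1:
                return Assignment("intron", winners[0].gene_id, best)
            return Assignment("ambiguous")
    return Assignment("no_feature")


class _FeatureIndex:
    """Interval index of feature spans, one tree per chromosome."""

    def __init__(self, features: Sequence[Feature]):
        self.trees: dict[str, IntervalTree] = {}
        for f in features:
            span = f.span
            self.trees.setdefault(span.chrom, IntervalTree()).addi(
                span.start, span.end, f
            )

    def candidates(self, read: AlignedRead) -> list[Feature]:
        tree = self.trees.get(read.chrom)
        if tree is None:
            return []
        found: dict[int, Feature] = {}
        for b in read.blocks:
            for hit in tree.overlap(b.start, b.end):
                found[id(hit.data)] = hit.data
        # deterministic order regardless of tree internals
        return sorted(found.values(), key=_feature_id)


def _features_at_level(
    annotation: Sequence[GeneModel], level: str
) -> list[Feature]:
    if level == "gene":
        return list(annotation)
    return [t for g in annotation for t in g.transcripts]


def count_sample(
    reads: Iterable[AlignedRead],
    annotation: Sequence[GeneModel],
    cfg: Optional[CounterConfig] = None,
    sample_id: str = "sample",
) -> CountTable:
    """Count one sample's reads against an annotation.

    Returns a single-column :class:`CountTable` with per-feature exon
    counts, per-gene intron counts (gene level, when enabled) and the
    special counters.  With ``transcript_ambiguous_multicount`` every
    transcript a read exonically overlaps is incremented and the read is
    never placed in ambiguous.
    """
    cfg = cfg or CounterConfig()
    features = _features_at_level(annotation, cfg.level)
    feature_ids = [_feature_id(f) for f in features]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("duplicate feature IDs in annotation")
    index = _FeatureIndex(features)

    fcounts = dict.fromkeys(feature_ids, 0)
    gene_ids = [g.gene_id for g in annotation]
    icounts = dict.fromkeys(gene_ids, 0)
    special = dict.fromkeys(SPECIAL_COUNTERS, 0)
    missing_chroms: set[str] = set()

    for read in reads:
        candidates = index.candidates(read)
        if not candidates and read.chrom not in index.trees:
            if read.chrom not in missing_chroms:
                missing_chroms.add(read.chrom)
                logger.warning(
                    "chromosome %s present in reads but absent from annotation",
                    read.chrom,
                )
        if (
            cfg.level == "transcript"
            and cfg.transcript_ambiguous_multicount
            and read.n_hits == 1
            and read.mapq >= cfg.min_mapq
        ):
            overlapped = [
                f for f in candidates if overlap_bases(read, _exonic(f)) > 0
            ]
            if overlapped:
                for f in overlapped:
                    fcounts[_feature_id(f)] += 1
                continue
            special["no_feature"] += 1
            continue

        a = assign_read(read, candidates, cfg)
        if a.category == "feature":
            fcounts[a.feature_id] += 1
        elif a.category == "intron":
            icounts[a.feature_id] += 1
        else:
            special[a.category] += 1

    counts = np.array([[fcounts[f]] for f in feature_ids], dtype=np.int64)
    intron_ids: list[str] = []
    intron_counts = None
    if cfg.count_introns and cfg.level == "gene":
        intron_ids = gene_ids
        intron_counts = np.array([[icounts[g]] for g in gene_ids], dtype=np.int64)
    return CountTable(
        feature_ids=feature_ids,
        sample_ids=[sample_id],
        counts=counts,
        intron_gene_ids=intron_ids,
        intron_counts=intron_counts,
        special_counts={k: np.array([v]) for k, v in special.items()},
    )


def merge_samples(tables: Sequence[CountTable]) -> CountTable:
    """Column-bind single-sample tables sharing one feature list."""
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        if t.feature_ids != first.feature_ids:
            raise ValueError("feature lists differ between samples")
        if t.intron_gene_ids != first.intron_gene_ids:
            raise ValueError("intron row lists differ between samples")
    sample_ids = [s for t in tables for s in t.sample_ids]
    counts = np.hstack([t.counts for t in tables])
    intron_counts = None
    if first.intron_counts is not None:
        intron_counts = np.hstack([t.intron_counts for t in tables])
    special = {}
    for name in SPECIAL_COUNTERS:
        if all(name in t.special_counts for t in tables):
            special[name] = np.concatenate([t.special_counts[name] for t in tables])
    return CountTable(
        feature_ids=list(first.feature_ids),
        sample_ids=sample_ids,
        counts=counts,
        intron_gene_ids=list(first.intron_gene_ids),
        intron_counts=intron_counts,
        special_counts=special,
    )
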