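"""Sample QC gating, total-count normalization and the expression filter.

Samples enter the map only if they carry at least 10 million reads of
which at least 60% mapped.  Expression is normalized per sample by the
combined count of all features (reads not assigned to a feature —
introns, ambiguous, unmapped — are excluded from both numerator and
denominator).  Features lacking >= ``min_reads`` raw reads in at least
``min_sample_fraction`` of samples are excluded before any correlation
work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .models import CoexmapError, CountTable, ExpressionMatrix


@dataclass
class QcThresholds:
    min_total_reads: int = 10_000_000
    min_mapped_fraction: float = 0.60

    def __post_init__(self):
        if self.min_total_reads <= 0:
            raise ValueError("min_total_reads must be positive")
        if not (0 < self.min_mapped_fraction <= 1):
            raise ValueError("min_mapped_fraction must be in (0, 1]")


@dataclass
class FilterParams:
    min_reads: int = 10
    min_sample_fraction: float = 0.10

    def __post_init__(self):
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not (0 <= self.min_sample_fraction <= 1):
            raise ValueError("min_sample_fraction must be in [0, 1]")


@dataclass
class QcResult:
    passed: bool
    reason: str = ""


def sample_qc(
    stats: Mapping[str, Mapping[str, int]],
    thresholds: QcThresholds | None = None,
) -> dict[str, QcResult]:
    """Gate samples on total read count and mapped fraction.

    ``stats`` maps sample ID to ``{"total_reads": int, "mapped_reads": int}``.
    Boundary values pass (a sample with exactly ``min_total_reads`` reads
    and exactly ``min_mapped_fraction`` mapped is kept).
    """
    thresholds = thresholds or QcThresholds()
    out: dict[str, QcResult] = {}
    for sample, st in stats.items():
        total = int(st["total_reads"])
        mapped = int(st["mapped_reads"])
        if mapped > total:
            raise ValueError(f"sample {sample}: mapped_reads > total_reads")
        if total == 0:
            out[sample] = QcResult(False, "empty")
        elif total < thresholds.min_total_reads:
            out[sample] = QcResult(
                False, f"total_reads {total} < {thresholds.min_total_reads}"
            )
        elif mapped / total < thresholds.min_mapped_fraction:
            out[sample] = QcResult(
                False,
                f"mapped fraction {mapped / total:.4f} < "
                f"{thresholds.min_mapped_fraction}",
            )
        else:
            out[sample] = QcResult(True)
    return out


def normalize(table: CountTable) -> ExpressionMatrix:
    """Divide each feature count by the sample's total feature count.

    Intron rows and the special counters live outside ``table.counts`` and
    therefore never enter numerator or denominator.
    """
    totals = table.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = ", ".join(table.sample_ids[i] for i in zero)
        raise CoexmapError(f"sample(s) with zero total feature count: {names}")
    values = table.counts / totals[np.newaxis, :]
    return ExpressionMatrix(
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
        values=values,
    )


def filter_features(
    table: CountTable, params: FilterParams | None = None
) -> list[str]:
    """Feature IDs expressed (raw count >= min_reads) in at least
    ``min_sample_fraction`` of samples; boundary fraction retained."""
    params = params or FilterParams()
    if table.n_samples < 1:
        raise ValueError("need at least one sample")
    expressed = (table.counts >= params.min_reads).sum(axis=1)
    frac = expressed / table.n_samples
    keep = frac >= params.min_sample_fraction
    return [f for f, k in zip(table.feature_ids, keep) if k]
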