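"""Guilt-by-association queries over a co-expression map.

A single-feature query reports the 50 strongest co-expressed genes
(ordered by mutual rank), the 25 strongest co-expressed transcription
factors, the top 20 locally computed functional-enrichment categories
among the top 1500 significantly co-expressed partners, and the most
negatively correlated partners.  Seed-list queries rank candidates by
mean forward rank across seeds or by a top-5% vote count.  Enrichment is
a hypergeometric upper-tail test with Bonferroni correction over the
terms represented in the background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .coexpression import NeighborEntry


@dataclass
class QueryConfig:
    n_top_genes: int = 50
    n_top_tfs: int = 25
    n_enrichment_terms: int = 20
    enrichment_query_size: int = 1500
    alpha: float = 0.05
    top_fraction: float = 0.05
    effective_n: str = "samples"  # or "sum_weights"

    def __post_init__(self):
        for name in (
            "n_top_genes",
            "n_top_tfs",
            "n_enrichment_terms",
            "enrichment_query_size",
            "alpha",
            "top_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.top_fraction > 1:
            raise ValueError("top_fraction must be <= 1")


@dataclass
class CorrelationTest:
    r: float
    n: int
    t_statistic: float
    p_value: float
    bonferroni_cutoff: Optional[float] = None
    degenerate: bool = False  # |r| = 1: p pinned to 0


@dataclass
class EnrichmentRow:
    term: str
    query_hits: int
    query_size: int
    term_size_in_background: int
    background_size: int
    p: float
    p_bonferroni: float


@dataclass
class QueryReport:
    query_ids: list[str]
    top_genes: list[NeighborEntry]
    top_tfs: list[NeighborEntry]
    enrichment: list[EnrichmentRow]
    negative: list[NeighborEntry]
    notes: list[str] = field(default_factory=list)


def correlation_pvalue(
    r: float, n: int, n_features: Optional[int] = None, alpha: float = 0.05
) -> CorrelationTest:
    """Two-sided p-value of a Pearson correlation via the t transform.

    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.  |r| = 1 is
    returned with p = 0 and the ``degenerate`` flag set.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    cutoff = alpha / n_features if n_features else None
    if abs(r) >= 1.0:
        return CorrelationTest(r, n, math.inf * np.sign(r), 0.0, cutoff, True)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationTest(r, n, t, float(min(p, 1.0)), cutoff)


def top_fraction_size(n: int, frac: float = 0.05) -> int:
    """Partner-list length for the top ``frac`` of an ``n``-feature map.

    Ceiling of frac*n with the product snapped to 9 decimals first so
    binary-float residue cannot inflate an exact product; minimum 1.
    A 114,936-feature map at 5% gives 5,747.
    """
    if frac <= 0:
        raise ValueError("fraction must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(1, math.ceil(round(frac * n, 9)))


def enrich(
    query_set: set[str],
    background: set[str],
    annotations: Mapping[str, set[str]],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each term in ``query_set``.

    Population = background, successes = term members in background,
    draws = query size; p = P(X >= k).  Bonferroni multiplies by the
    number of terms with at least one background member.  Terms without
    query hits are reported with p = 1.
    """
    if not background:
        raise ValueError("empty background")
    if not query_set <= background:
        raise ValueError("query set must be a subset of the background")
    n_bg = len(background)
    n_q = len(query_set)
    tested = {
        term: members & background
        for term, members in annotations.items()
        if members & background
    }
    m = len(tested)
    rows = []
    for term, members in tested.items():
        big_k = len(members)
        k = len(members & query_set)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_q))
            p = min(max(p, 0.0), 1.0)
        rows.append(
            EnrichmentRow(
                term=term,
                query_hits=k,
                query_size=n_q,
                term_size_in_background=big_k,
                background_size=n_bg,
                p=p,
                p_bonferroni=min(1.0, p * m),
            )
        )
    rows.sort(key=lambda row: (row.p, row.term))
    return rows


def query_single(
    cmap,
    feature_id: str,
    tf_ids: Optional[set[str]] = None,
    annotations: Optional[Mapping[str, set[str]]] = None,
    cfg: Optional[QueryConfig] = None,
) -> QueryReport:
    """The full report for one query feature."""
    cfg = cfg or QueryConfig()
    tf_ids = tf_ids or set()
    ordered = cmap.neighbors(feature_id, k=cmap.n_features - 1)

    top_genes = ordered[: cfg.n_top_genes]
    top_tfs = [e for e in ordered if e.neighbor_id in tf_ids][: cfg.n_top_tfs]
    negative = cmap.negative_neighbors(feature_id, k=cfg.n_top_genes)

    notes = [f"query={feature_id}", f"ordering=mutual_rank:{cmap.mr_rule}"]
    enrichment: list[EnrichmentRow] = []
    if annotations:
        cutoff = cfg.alpha / cmap.n_features
        significant = []
        for e in ordered[: cfg.enrichment_query_size]:
            test = correlation_pvalue(e.r, cmap.n_samples)
            if test.p_value < cutoff:
                significant.append(e.neighbor_id)
        notes.append(
            f"enrichment_query={len(significant)} partners with p < "
            f"{cutoff:.3g} (alpha/{cmap.n_features})"
        )
        if significant:
            background = set(cmap.feature_ids)
            enrichment = enrich(set(significant), background, annotations)[
                : cfg.n_enrichment_terms
            ]
    return QueryReport(
        query_ids=[feature_id],
        top_genes=top_genes,
        top_tfs=top_tfs,
        enrichment=enrichment,
        negative=negative,
        notes=notes,
    )


def query_set(
    cmap,
    seeds: Sequence[str],
    method: str = "mean_rank",
    cfg: Optional[QueryConfig] = None,
) -> tuple[list[tuple[str, float]], list[str]]:
    """Rank non-seed candidates against a seed list.

    ``mean_rank``: score = mean forward rank of the candidate across the
    seeds' partner lists (lower is better; a candidate missing from a
    stored list contributes rank N).  ``vote``: score = number of seeds
    whose top-5% list contains the candidate (higher is better).
    Returns (ranked [(candidate, score)], missing seeds).
    """
    cfg = cfg or QueryConfig()
    if method not in ("mean_rank", "vote"):
        raise ValueError(f"unknown method {method!r}")
    known = set(cmap.feature_ids)
    found = [s for s in seeds if s in known]
    missing = [s for s in seeds if s not in known]
    if not found:
        raise ValueError("no seed found in the map")
    seed_set = set(found)
    n = cmap.n_features

    scores: dict[str, float] = {}
    if method == "mean_rank":
        totals: dict[str, float] = {}
        for seed in found:
            ranked = {
                e.neighbor_id: e.rank_forward
                for e in cmap.neighbors(seed, k=n - 1)
                if e.rank_forward is not None
            }
            for fid in cmap.feature_ids:
                if fid in seed_set:
                    continue
                totals[fid] = totals.get(fid, 0.0) + ranked.get(fid, n)
        scores = {fid: total / len(found) for fid, total in totals.items()}
        ranked_out = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    else:
        k = top_fraction_size(n, cfg.top_fraction)
        votes: dict[str, int] = {
            fid: 0 for fid in cmap.feature_ids if fid not in seed_set
        }
        for seed in found:
            for e in cmap.neighbors(seed, k=k):
                if e.neighbor_id not in seed_set:
                    votes[e.neighbor_id] += 1
        ranked_out = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked_out, missing


def partner_overlap(
    cmap, a: str, b: str, frac: float = 0.05
) -> dict[str, float]:
    """Overlap of two features' top-``frac`` partner lists.

    The list size is taken from the full map size N (a 114,936-feature
    map at 5% compares lists of 5,747); the queried pair itself is
    excluded from both lists before intersecting.
    """
    if a == b:
        raise ValueError("partner_overlap requires two distinct features")
    size = top_fraction_size(cmap.n_features, frac)
    k = min(size, cmap.n_features - 2)
    # the queried pair is excluded before truncation so that two identical
    # features share their entire lists (fraction 1.0)
    list_a = [e.neighbor_id for e in cmap.neighbors(a, k=k + 1) if e.neighbor_id != b]
    list_b = [e.neighbor_id for e in cmap.neighbors(b, k=k + 1) if e.neighbor_id != a]
    shared = len(set(list_a[:k]) & set(list_b[:k]))
    return {
        "shared": shared,
        "list_size": size,
        "fraction": shared / size,
    }
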