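"""Redundancy-weighted co-expression map with mutual ranks.

The map is built COXPRESdb-style: samples that are near-duplicates of
each other (inter-sample Pearson correlation >= a threshold tau) are
down-weighted by the inverse of their similar-sample count, a weighted
Pearson correlation is computed for every feature pair, each feature's
partners are ranked by correlation, and the mutual rank of a pair is the
average of the two directional ranks.  Mutual rank de-prioritizes
promiscuous hubs (e.g. ribosomal genes) that correlate strongly with
everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .models import CoexmapError, ExpressionMatrix

LOG_PSEUDOCOUNT = 1e-8


@dataclass
class SampleWeights:
    """Per-sample weights w_i = 1 / (number of samples similar to i).

    A sample is always similar to itself, so n_i >= 1 and w_i <= 1.
    """

    sample_ids: list[str]
    weights: np.ndarray
    similarity_threshold: float = 1.0
    similar_counts: Optional[np.ndarray] = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.sample_ids),):
            raise ValueError("weights length mismatch")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")

    @classmethod
    def uniform(cls, sample_ids: Sequence[str]) -> "SampleWeights":
        n = len(sample_ids)
        return cls(
            list(sample_ids),
            np.ones(n),
            similarity_threshold=1.0,
            similar_counts=np.ones(n, dtype=int),
        )


@dataclass
class NeighborEntry:
    neighbor_id: str
    r: float
    rank_forward: Optional[int]
    rank_backward: Optional[int]
    mutual_rank: Optional[float]


def sample_similarity(expr: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation between sample columns (symmetric, unit diagonal)."""
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if expr.n_features < 3:
        raise ValueError("need at least 3 features")
    sd = expr.values.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(expr.sample_ids[i] for i in zero)
        raise CoexmapError(f"zero-variance sample column(s): {names}")
    S = np.corrcoef(expr.values, rowvar=False)
    np.fill_diagonal(S, 1.0)
    return S


def redundancy_weights(
    S: np.ndarray,
    tau: float = 0.95,
    sample_ids: Optional[Sequence[str]] = None,
) -> SampleWeights:
    """Invert the per-sample similar-sample count at threshold ``tau``."""
    if tau > 1:
        raise ValueError("tau must be <= 1")
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    n = S.shape[0]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    counts = (S >= tau).sum(axis=1)
    counts = np.maximum(counts, 1)  # self always similar
    return SampleWeights(
        list(sample_ids),
        1.0 / counts,
        similarity_threshold=tau,
        similar_counts=counts.astype(int),
    )


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation; invariant to rescaling of ``w``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape) or x.ndim != 1:
        raise ValueError("x, y, w must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    wsum = w.sum()
    xm = (w * x).sum() / wsum
    ym = (w * y).sum() / wsum
    xd = x - xm
    yd = y - ym
    vx = (w * xd * xd).sum()
    vy = (w * yd * yd).sum()
    if vx <= 0 or vy <= 0:
        raise CoexmapError("zero weighted variance")
    return float((w * xd * yd).sum() / math.sqrt(vx * vy))


class CoexpressionMap:
    """All-pairs weighted correlations plus directional and mutual ranks.

    Holds the full N x N correlation and rank matrices in memory; the
    serialized form (see :func:`save_map`) keeps only the top/bottom
    neighbor lists.
    """

    def __init__(
        self,
        feature_ids: Sequence[str],
        r_matrix: np.ndarray,
        rank_matrix: np.ndarray,
        weights: SampleWeights,
        n_samples: int,
        k_top: int,
        k_neg: int,
        mr_rule: str = "arithmetic",
    ):
        self.feature_ids = list(feature_ids)
        self._index = {f: i for i, f in enumerate(self.feature_ids)}
        self.r_matrix = r_matrix
        self.rank_matrix = rank_matrix
        self.weights = weights
        self.n_samples = n_samples
        self.k_top = k_top
        self.k_neg = k_neg
        self.mr_rule = mr_rule

    # -- basic lookups ----------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def _i(self, feature_id: str) -> int:
        try:
            return self._index[feature_id]
        except KeyError:
            close = sorted(
                self.feature_ids, key=lambda f: (f[:4] != feature_id[:4], f)
            )[:3]
            raise KeyError(
                f"unknown feature {feature_id!r}; nearest: {', '.join(close)}"
            ) from None

    def r(self, a: str, b: str) -> float:
        return float(self.r_matrix[self._i(a), self._i(b)])

    def rank_forward(self, a: str, b: str) -> int:
        """Rank of b in a's correlation-sorted partner list (1 = closest)."""
        ia, ib = self._i(a), self._i(b)
        if ia == ib:
            raise ValueError("self-rank is undefined")
        return int(self.rank_matrix[ia, ib])

    def mutual_rank(self, a: str, b: str) -> float:
        fwd = self.rank_forward(a, b)
        bwd = self.rank_forward(b, a)
        if self.mr_rule == "geometric":
            return math.sqrt(fwd * bwd)
        return (fwd + bwd) / 2.0

    # -- neighbor lists ----------------------------------------------------
    def _entries(self, i: int, order: np.ndarray) -> list[NeighborEntry]:
        out = []
        for j in order:
            fwd = int(self.rank_matrix[i, j])
            bwd = int(self.rank_matrix[j, i])
            mr = (
                math.sqrt(fwd * bwd)
                if self.mr_rule == "geometric"
                else (fwd + bwd) / 2.0
            )
            out.append(
                NeighborEntry(self.feature_ids[j], float(self.r_matrix[i, j]), fwd, bwd, mr)
            )
        return out

    def neighbors(self, feature_id: str, k: Optional[int] = None) -> list[NeighborEntry]:
        """Top partners sorted by mutual rank ascending (ties: r descending,
        then neighbor ID ascending)."""
        i = self._i(feature_id)
        n = self.n_features
        k = min(k if k is not None else self.k_top, n - 1)
        others = np.array([j for j in range(n) if j != i])
        fwd = self.rank_matrix[i, others].astype(float)
        bwd = self.rank_matrix[others, i].astype(float)
        if self.mr_rule == "geometric":
            mr = np.sqrt(fwd * bwd)
        else:
            mr = (fwd + bwd) / 2.0
        ids = np.array([self.feature_ids[j] for j in others])
        sort = np.lexsort((ids, -self.r_matrix[i, others], mr))
        return self._entries(i, others[sort[:k]])

    def negative_neighbors(
        self, feature_id: str, k: Optional[int] = None
    ) -> list[NeighborEntry]:
        """Bottom partners sorted by r ascending (ties: neighbor ID)."""
        i = self._i(feature_id)
        n = self.n_features
        k = min(k if k is not None else self.k_neg, n - 1)
        others = np.array([j for j in range(n) if j != i])
        ids = np.array([self.feature_ids[j] for j in others])
        sort = np.lexsort((ids, self.r_matrix[i, others]))
        return self._entries(i, others[sort[:k]])


def build_map(
    expr: ExpressionMatrix,
    weights: Optional[SampleWeights] = None,
    k_top: Optional[int] = None,
    k_neg: Optional[int] = None,
    mr_rule: str = "arithmetic",
    log_transform: bool = False,
) -> CoexpressionMap:
    """Compute all N(N-1)/2 weighted correlations and both rank directions.

    ``expr`` must already be filtered; a constant feature row is an error.
    Default list sizes: k_top = max(ceil(0.05 N), 1500, 50), k_neg = 1500,
    both clamped to N - 1.
    """
    if mr_rule not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mr_rule {mr_rule!r}")
    n = expr.n_features
    if n < 3:
        raise ValueError("need at least 3 features")
    if weights is None:
        weights = SampleWeights.uniform(expr.sample_ids)
    if list(weights.sample_ids) != list(expr.sample_ids):
        raise ValueError("weights sample order does not match matrix")

    X = expr.values
    if log_transform:
        X = np.log10(X + LOG_PSEUDOCOUNT)
    w = weights.weights
    wsum = w.sum()
    means = X @ w / wsum
    Xc = X - means[:, None]
    var = (Xc * Xc) @ w
    constant = np.all(X == X[:, [0]], axis=1)
    flat = np.flatnonzero(constant | (var <= 0))
    if flat.size:
        raise CoexmapError(
            f"constant feature row(s): {', '.join(expr.feature_ids[i] for i in flat)}"
        )
    C = (Xc * w) @ Xc.T
    d = np.sqrt(var)
    R = C / np.outer(d, d)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)

    # directional ranks; ties broken by neighbor ID ascending
    id_rank = np.argsort(np.argsort(np.array(expr.feature_ids)))
    rank = np.zeros((n, n), dtype=np.int32)
    all_idx = np.arange(n)
    for i in range(n):
        others = all_idx[all_idx != i]
        order = others[np.lexsort((id_rank[others], -R[i, others]))]
        rank[i, order] = np.arange(1, n, dtype=np.int32)

    if k_top is None:
        k_top = max(math.ceil(0.05 * n), 1500, 50)
    if k_neg is None:
        k_neg = 1500
    if k_top <= 0 or k_neg <= 0:
        raise ValueError("k_top and k_neg must be positive")
    k_top = min(k_top, n - 1)
    k_neg = min(k_neg, n - 1)

    return CoexpressionMap(
        feature_ids=expr.feature_ids,
        r_matrix=R,
        rank_matrix=rank,
        weights=weights,
        n_samples=expr.n_samples,
        k_top=k_top,
        k_neg=k_neg,
        mr_rule=mr_rule,
    )


def pair_lookup(cmap: CoexpressionMap, a: str, b: str) -> NeighborEntry:
    """Correlation, both directional ranks and MR for one pair."""
    if a == b:
        raise ValueError("pair_lookup requires two distinct features")
    return NeighborEntry(
        neighbor_id=b,
        r=cmap.r(a, b),
        rank_forward=cmap.rank_forward(a, b),
        rank_backward=cmap.rank_forward(b, a),
        mutual_rank=cmap.mutual_rank(a, b),
    )


# ---------------------------------------------------------------------------
# Serialization: neighbors TSV + key-value metadata sidecar

def save_map(cmap: CoexpressionMap, prefix: Union[str, Path]) -> None:
    """Write ``<prefix>.neighbors.tsv``, ``<prefix>.features.txt`` and
    ``<prefix>.meta.txt``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.neighbors.tsv", "w") as fh:
        fh.write("query_id\tneighbor_id\tlist\tr\trank_fwd\trank_bwd\tmutual_rank\n")
        for fid in cmap.feature_ids:
            for tag, entries in (
                ("top", cmap.neighbors(fid)),
                ("bottom", cmap.negative_neighbors(fid)),
            ):
                for e in entries:
                    fh.write(
                        f"{fid}\t{e.neighbor_id}\t{tag}\t{e.r:.10g}\t"
                        f"{e.rank_forward}\t{e.rank_backward}\t{e.mutual_rank:.10g}\n"
                    )
    with open(f"{prefix}.features.txt", "w") as fh:
        fh.write("\n".join(cmap.feature_ids) + "\n")
    with open(f"{prefix}.meta.txt", "w") as fh:
        for key, val in (
            ("n_features", cmap.n_features),
            ("n_samples", cmap.n_samples),
            ("k_top", cmap.k_top),
            ("k_neg", cmap.k_neg),
            ("mr_rule", cmap.mr_rule),
            ("similarity_threshold", cmap.weights.similarity_threshold),
        ):
            fh.write(f"{key}={val}\n")


class StoredMap:
    """Query-side view of a serialized map (stored neighbor lists only).

    Exposes the same query surface as :class:`CoexpressionMap`; pair
    lookups outside the stored lists return ``None`` ranks.
    """

    def __init__(
        self,
        feature_ids: list[str],
        top: dict[str, list[NeighborEntry]],
        bottom: dict[str, list[NeighborEntry]],
        n_samples: int,
        k_top: int,
        k_neg: int,
        mr_rule: str,
    ):
        self.feature_ids = feature_ids
        self._index = set(feature_ids)
        self._top = top
        self._bottom = bottom
        self.n_samples = n_samples
        self.k_top = k_top
        self.k_neg = k_neg
        self.mr_rule = mr_rule

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def _check(self, feature_id: str) -> None:
        if feature_id not in self._index:
            raise KeyError(f"unknown feature {feature_id!r}")

    def neighbors(self, feature_id: str, k: Optional[int] = None) -> list[NeighborEntry]:
        self._check(feature_id)
        entries = self._top.get(feature_id, [])
        return entries[: k if k is not None else self.k_top]

    def negative_neighbors(
        self, feature_id: str, k: Optional[int] = None
    ) -> list[NeighborEntry]:
        self._check(feature_id)
        entries = self._bottom.get(feature_id, [])
        return entries[: k if k is not None else self.k_neg]

    def rank_forward(self, a: str, b: str) -> Optional[int]:
        self._check(a)
        self._check(b)
        for e in self._top.get(a, []):
            if e.neighbor_id == b:
                return e.rank_forward
        return None

    def r(self, a: str, b: str) -> Optional[float]:
        self._check(a)
        self._check(b)
        for e in self._top.get(a, []) + self._bottom.get(a, []):
            if e.neighbor_id == b:
                return e.r
        return None


def load_map(prefix: Union[str, Path]) -> StoredMap:
    prefix = Path(prefix)
    meta: dict[str, str] = {}
    with open(f"{prefix}.meta.txt") as fh:
        for line in fh:
            if "=" in line:
                key, val = line.rstrip("\n").split("=", 1)
                meta[key] = val
    with open(f"{prefix}.features.txt") as fh:
        feature_ids = [ln.strip() for ln in fh if ln.strip()]
    top: dict[str, list[NeighborEntry]] = {}
    bottom: dict[str, list[NeighborEntry]] = {}
    with open(f"{prefix}.neighbors.tsv") as fh:
        header = fh.readline()
        for line in fh:
            q, nb, tag, r, fwd, bwd, mr = line.rstrip("\n").split("\t")
            entry = NeighborEntry(nb, float(r), int(fwd), int(bwd), float(mr))
            (top if tag == "top" else bottom).setdefault(q, []).append(entry)
    return StoredMap(
        feature_ids=feature_ids,
        top=top,
        bottom=bottom,
        n_samples=int(meta["n_samples"]),
        k_top=int(meta["k_top"]),
        k_neg=int(meta["k_neg"]),
        mr_rule=meta.get("mr_rule", "arithmetic"),
    )
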