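"""Scrambled-data null model, ROC construction and FDR-at-sensitivity.

To estimate how often an observed correlation of a given strength would
arise between unrelated features, each feature row is independently
permuted across samples (destroying covariance while preserving every
marginal), the correlations of the scrambled matrix are taken as
negatives and the correlations of the true matrix as positives, and an
ROC curve is swept over the union of observed values.  The FDR at a
sensitivity level (e.g. 95%) is reported together with the correlation
threshold at which that sensitivity is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coexpression import SampleWeights, weighted_pearson
from .models import ExpressionMatrix


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray  # fraction of positives >= threshold
    fpr: np.ndarray  # fraction of negatives >= threshold
    auc: float
    fdr: np.ndarray = field(default=None)  # FP/(FP+TP), populations rescaled
    fdr_at: dict[float, tuple[float, float]] = field(default_factory=dict)


def scramble(
    expr: ExpressionMatrix, seed: int, mode: str = "row"
) -> ExpressionMatrix:
    """Permute expression values with a seeded generator.

    ``row`` (default): each feature row permuted independently across
    samples — the standard correlation null.  ``global``: one shuffle of
    the whole matrix.
    """
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    if mode == "row":
        for i in range(values.shape[0]):
            values[i, :] = values[i, rng.permutation(values.shape[1])]
    elif mode == "global":
        flat = values.ravel()
        rng.shuffle(flat)
        values = flat.reshape(expr.values.shape)
    else:
        raise ValueError(f"unknown scramble mode {mode!r}")
    return ExpressionMatrix(
        list(expr.feature_ids), list(expr.sample_ids), values
    )


def roc_from_value_sets(
    positives: Sequence[float],
    negatives: Sequence[float],
    sensitivity_levels: Sequence[float] = (0.95,),
) -> RocCurve:
    """Sweep thresholds over the union of observed values.

    At each threshold t: sensitivity = |{p >= t}| / |P| and
    fpr = |{n >= t}| / |N|.  AUC is the trapezoid over (fpr, sensitivity)
    with (0,0)/(1,1) endpoints.  FDR is computed from rates, i.e. with
    both populations rescaled to equal size.
    """
    pos = np.sort(np.asarray(positives, dtype=float))
    neg = np.sort(np.asarray(negatives, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positives and negatives must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    # count of values >= t via searchsorted on the ascending sorted arrays
    sens = (pos.size - np.searchsorted(pos, thresholds, side="left")) / pos.size
    fpr = (neg.size - np.searchsorted(neg, thresholds, side="left")) / neg.size
    x = np.concatenate([[0.0], fpr, [1.0]])
    y = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(y, x))
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_fdr = np.where(sens + fpr > 0, fpr / (fpr + sens), 0.0)
    # interpolate as for precision-recall curves: report at each threshold
    # the best FDR achievable at an equal-or-more-lenient threshold, which
    # makes FDR non-increasing as the threshold rises
    fdr = np.minimum.accumulate(raw_fdr[::-1])[::-1]
    curve = RocCurve(thresholds, sens, fpr, auc, fdr)
    for level in sensitivity_levels:
        curve.fdr_at[level] = fdr_at_sensitivity(curve, level)
    return curve


def fdr_at_sensitivity(roc: RocCurve, level: float) -> tuple[float, float]:
    """(fdr, threshold) at the first threshold — sweeping strict to lenient —
    whose sensitivity reaches ``level``."""
    if not (0 < level <= 1):
        raise ValueError("sensitivity level must be in (0, 1]")
    idx = np.flatnonzero(roc.sensitivity >= level)
    if idx.size == 0:
        raise ValueError(f"sensitivity {level} not reachable")
    i = idx[0]
    return float(roc.fdr[i]), float(roc.thresholds[i])


def _pair_sample(
    rng: np.random.Generator, n_features: int, n_pairs: int
) -> np.ndarray:
    """Seeded sample of distinct unordered feature pairs (all pairs when
    n_pairs covers them)."""
    total = n_features * (n_features - 1) // 2
    if n_pairs >= total or total <= 5_000_000:
        iu, ju = np.triu_indices(n_features, k=1)
        if n_pairs >= total:
            return np.column_stack([iu, ju])
        idx = rng.choice(total, size=n_pairs, replace=False)
        return np.column_stack([iu[idx], ju[idx]])
    # large maps: rejection-sample distinct unordered pairs
    seen: set[tuple[int, int]] = set()
    while len(seen) < n_pairs:
        a, b = rng.integers(0, n_features, size=2)
        if a != b:
            seen.add((min(a, b), max(a, b)))
    return np.array(sorted(seen), dtype=int)


def _pair_correlations(
    values: np.ndarray, pairs: np.ndarray, w: np.ndarray
) -> np.ndarray:
    wsum = w.sum()
    means = values @ w / wsum
    Xc = values - means[:, None]
    var = (Xc * Xc) @ w
    num = ((Xc[pairs[:, 0]] * Xc[pairs[:, 1]]) * w).sum(axis=1)
    den = np.sqrt(var[pairs[:, 0]] * var[pairs[:, 1]])
    return np.clip(num / den, -1.0, 1.0)


def calibrate(
    expr: ExpressionMatrix,
    weights: Optional[SampleWeights] = None,
    seed: int = 0,
    n_pairs: int = 10_000,
    sensitivity_levels: Sequence[float] = (0.95,),
    scramble_mode: str = "row",
    positives: str = "all",
) -> RocCurve:
    """Positives: weighted correlations of seeded random pairs from the true
    matrix.  Negatives: a same-size sample from the scrambled matrix.

    ``positives="all"`` takes every sampled true-matrix correlation as a
    positive; ``"top5"`` keeps only the strongest 5%, mirroring a map
    that stores each feature's top-5% partner lists so that only strong
    values are "present in the map".  The two readings answer different
    questions: "all" measures whether any true structure exists (0.5 on
    null data), "top5" measures how separable the stored co-expression
    values are from scrambled-data values.
    """
    if n_pairs < 100:
        raise ValueError("n_pairs < 100 gives an unstable estimate")
    if positives not in ("all", "top5"):
        raise ValueError(f"unknown positives rule {positives!r}")
    if weights is None:
        weights = SampleWeights.uniform(expr.sample_ids)
    rng = np.random.default_rng(seed)
    pairs_true = _pair_sample(rng, expr.n_features, n_pairs)
    pairs_null = _pair_sample(rng, expr.n_features, n_pairs)
    scrambled = scramble(expr, seed=int(rng.integers(0, 2**31 - 1)), mode=scramble_mode)
    w = weights.weights
    pos = _pair_correlations(expr.values, pairs_true, w)
    neg = _pair_correlations(scrambled.values, pairs_null, w)
    if positives == "top5":
        keep = max(int(np.ceil(0.05 * pos.size)), 1)
        pos = np.sort(pos)[-keep:]
    return roc_from_value_sets(pos, neg, sensitivity_levels)
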