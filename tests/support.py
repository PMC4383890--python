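"""Independent oracles shared by the test suite.

Everything here is written as plain loops over definitions, deliberately
avoiding the vectorized code paths in the package so the two can
disagree when one of them is wrong.
"""

import math

import numpy as np

import coexmap as cm


def random_expression(seed: int, n_features: int, n_samples: int) -> cm.ExpressionMatrix:
    rng = np.random.default_rng(seed)
    values = rng.gamma(2.0, 1.0, size=(n_features, n_samples)) + 1e-6
    values /= values.sum(axis=0, keepdims=True)
    return cm.ExpressionMatrix(
        [f"g{i:03d}" for i in range(n_features)],
        [f"s{j:03d}" for j in range(n_samples)],
        values,
    )


def tiny_map(seed: int, n: int, n_samples: int = 12) -> cm.CoexpressionMap:
    expr = random_expression(seed, n, n_samples)
    return cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))


def weighted_pearson_loops(x, y, w) -> float:
    """Definition-level weighted correlation (scalar loops)."""
    sw = sum(w)
    xm = sum(wi * xi for wi, xi in zip(w, x)) / sw
    ym = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - xm) * (yi - ym) for wi, xi, yi in zip(w, x, y))
    vx = sum(wi * (xi - xm) ** 2 for wi, xi in zip(w, x))
    vy = sum(wi * (yi - ym) ** 2 for wi, yi in zip(w, y))
    return cov / math.sqrt(vx * vy)


def brute_force_map(expr: cm.ExpressionMatrix, weights: cm.SampleWeights):
    """All-pairs map by scalar loops: returns (r, rank_fwd, mr) dicts keyed by
    ordered ID pairs."""
    ids = expr.feature_ids
    w = list(weights.weights)
    r = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                val = weighted_pearson_loops(
                    list(expr.values[i]), list(expr.values[j]), w
                )
                r[(a, b)] = val
                r[(b, a)] = val
    rank = {}
    for a in ids:
        order = sorted(
            (b for b in ids if b != a), key=lambda b: (-r[(a, b)], b)
        )
        for pos, b in enumerate(order, start=1):
            rank[(a, b)] = pos
    mr = {
        (a, b): (rank[(a, b)] + rank[(b, a)]) / 2.0
        for a in ids
        for b in ids
        if a != b
    }
    return r, rank, mr


def roc_sweep_loops(positives, negatives):
    """Exhaustive threshold sweep from the definitions."""
    thresholds = sorted(set(positives) | set(negatives), reverse=True)
    sens = [sum(1 for p in positives if p >= t) / len(positives) for t in thresholds]
    fpr = [sum(1 for n in negatives if n >= t) / len(negatives) for t in thresholds]
    xs = [0.0] + fpr + [1.0]
    ys = [0.0] + sens + [1.0]
    auc = sum(
        (xs[i + 1] - xs[i]) * (ys[i + 1] + ys[i]) / 2.0 for i in range(len(xs) - 1)
    )
    return thresholds, sens, fpr, auc


def hypergeom_tail_enumeration(k: int, n_bg: int, big_k: int, n_q: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf with
    exact integer combinatorics."""
    denom = math.comb(n_bg, n_q)
    total = 0
    for j in range(k, min(big_k, n_q) + 1):
        total += math.comb(big_k, j) * math.comb(n_bg - big_k, n_q - j)
    return total / denom
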