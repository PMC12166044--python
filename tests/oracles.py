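"""Independent brute-force oracles used to cross-check the fast paths.

Everything here is written directly from the defining formulas with
explicit Python loops, deliberately independent of the vectorized
implementations in the package.
"""

from __future__ import annotations

import math

import numpy as np


def bicor_brute(x, y) -> float:
    """Biweight midcorrelation from its published estimator definition."""

    def weights(v):
        med = float(np.median(v))
        mad = float(np.median([abs(a - med) for a in v]))
        out = []
        for a in v:
            u = (a - med) / (9.0 * mad) if mad > 0 else 0.0
            w = (1 - u * u) ** 2 if abs(u) < 1 else 0.0
            out.append((a - med) * w)
        if mad == 0:  # Pearson fallback
            mean = sum(v) / len(v)
            out = [a - mean for a in v]
        return out

    xt = weights(list(map(float, x)))
    yt = weights(list(map(float, y)))
    num = sum(a * b for a, b in zip(xt, yt))
    den = math.sqrt(sum(a * a for a in xt) * sum(b * b for b in yt))
    return num / den


def tom_dissim_brute(a: np.ndarray) -> np.ndarray:
    """1 - TOM via triple loops."""
    n = a.shape[0]
    k = [sum(a[i][j] for j in range(n)) for i in range(n)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i][u] * a[u][j] for u in range(n))
            tom = (shared + a[i][j]) / (min(k[i], k[j]) + 1 - a[i][j])
            out[i][j] = 1 - tom
    return out


def connectivity_brute(a: np.ndarray) -> list[float]:
    n = a.shape[0]
    return [sum(a[i][j] for j in range(n)) for i in range(n)]


def mar_brute(a: np.ndarray) -> list[float]:
    n = a.shape[0]
    out = []
    for i in range(n):
        k = sum(a[i][j] for j in range(n))
        s = sum(a[i][j] ** 2 for j in range(n))
        out.append(s / k if k > 0 else float("nan"))
    return out


def clustering_brute(a: np.ndarray) -> list[float]:
    n = a.shape[0]
    out = []
    for i in range(n):
        num = 0.0
        for j in range(n):
            for l in range(n):
                if j != l and j != i and l != i:
                    num += a[i][j] * a[j][l] * a[l][i]
        k = sum(a[i][j] for j in range(n))
        s = sum(a[i][j] ** 2 for j in range(n))
        den = k * k - s
        out.append(num / den if den > 0 else float("nan"))
    return out


def density_brute(a: np.ndarray) -> float:
    n = a.shape[0]
    k = connectivity_brute(a)
    return sum(k) / (n * (n - 1))


def centralization_brute(a: np.ndarray) -> float:
    n = a.shape[0]
    k = connectivity_brute(a)
    return n / (n - 2) * (max(k) / (n - 1) - density_brute(a))


def heterogeneity_brute(a: np.ndarray) -> float:
    k = connectivity_brute(a)
    mean = sum(k) / len(k)
    var = sum((x - mean) ** 2 for x in k) / len(k)  # population variance
    return math.sqrt(var) / mean


def ssgsea_walk_brute(expression: list[float], in_set: list[bool], exponent: float) -> float:
    """Enumerated cumulative-difference walk for one sample.

    Genes are ordered by decreasing expression; the in-set cumulative
    mass is weighted by rank**exponent (rank = average rank of the
    expression value, largest value -> largest rank), the out-of-set
    mass is uniform; the score is the sum of the running differences.
    """
    n = len(expression)
    # average ranks, largest expression gets the largest rank
    order_asc = sorted(range(n), key=lambda i: expression[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and expression[order_asc[j + 1]] == expression[order_asc[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order_asc[t]] = avg
        i = j + 1
    walk_order = sorted(range(n), key=lambda i: -ranks[i])
    denom_in = sum(ranks[i] ** exponent for i in range(n) if in_set[i])
    n_out = sum(1 for i in range(n) if not in_set[i])
    score = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for i in walk_order:
        if in_set[i]:
            cum_in += ranks[i] ** exponent / denom_in
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


def confusion_metrics_brute(tp: int, tn: int, fp: int, fn: int):
    """Accuracy / MCC / F1 from the textbook formulas; None marks N/A."""
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    mcc = None
    if min(tp + fp, tn + fn, tp + fn, tn + fp) > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
    f1 = None
    if (tp + fn) > 0 and (tp + fp) > 0:
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else None
    return acc, mcc, f1
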