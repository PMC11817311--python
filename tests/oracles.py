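"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the library code paths (and numpy shortcuts
where feasible) so that agreement is a genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_moments(values) -> tuple[float, float, float, float]:
    """(mean, sd with n-1, skewness, excess kurtosis) by direct sums."""
    xs = [float(v) for v in values]
    n = len(xs)
    mean = sum(xs) / n
    ss = sum((x - mean) ** 2 for x in xs)
    sd = math.sqrt(ss / (n - 1)) if n > 1 else 0.0
    m2 = ss / n
    if m2 == 0.0:
        return mean, sd, 0.0, 0.0
    m3 = sum((x - mean) ** 3 for x in xs) / n
    m4 = sum((x - mean) ** 4 for x in xs) / n
    return mean, sd, m3 / m2 ** 1.5, m4 / m2 ** 2 - 3.0


def brute_extrema(values) -> int:
    """Exhaustive scan for strict interior local extrema."""
    xs = [float(v) for v in values]
    count = 0
    for i in range(1, len(xs) - 1):
        left = xs[i] - xs[i - 1]
        right = xs[i + 1] - xs[i]
        if left * right < 0:
            count += 1
    return count


def brute_diff_chain(values, fs: float, order: int) -> list[float]:
    """Repeated forward differences divided by dt, by explicit loops."""
    xs = [float(v) for v in values]
    for _ in range(order):
        xs = [(xs[i + 1] - xs[i]) * fs for i in range(len(xs) - 1)]
    return xs


def concordance_auc(labels, scores) -> float:
    """AUC as the O(n^2) pairwise concordance statistic (ties count 1/2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def trapezoid_roc_auc(fpr, tpr) -> float:
    """Direct trapezoidal integration of an ROC polyline."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    return float(np.trapezoid(tpr, fpr))
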