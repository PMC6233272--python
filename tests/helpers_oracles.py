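"""Independent brute-force oracles used to cross-check library-backed implementations."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up applied literally from its definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * m / rank_from_top
        running_min = min(running_min, value)
        q[idx] = min(running_min, 1.0)
    return q


def brute_upgma_heights(dist: np.ndarray) -> list[float]:
    """UPGMA merge heights by direct agglomeration over original pairwise distances."""
    n = dist.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def fisher_exact_enum(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration (math.comb only)."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(k: int) -> float:
        return (
            math.comb(row1, k) * math.comb(row2, col1 - k) / math.comb(n, col1)
        )

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def mann_whitney_exact_enum(x: list[float], y: list[float]) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(group_x: list[float], group_y: list[float]) -> float:
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in group_x for b in group_y)

    u_obs = u_stat(x, y)
    mu = nx * len(y) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), nx):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(gx, gy) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def pooled_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form pooled-variance two-sample t p-value from first principles."""
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2.0 * float(t_dist.sf(abs(t), n1 + n2 - 2))
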