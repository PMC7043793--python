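"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where practical, the libraries)
they are checking: rank-split enumeration for the Mann-Whitney test, DFS
enumeration of all simple paths for shortest distances, exhaustive
nearest-neighbor search for fans, and closed-form binomial-coefficient
arithmetic for Fisher's exact test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def mw_exact_oracle(x, y, alternative: str) -> float:
    """Exact Mann-Whitney p by enumerating every split of the pooled ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = x.size, y.size
    pooled = np.sort(np.concatenate([x, y]))
    assert np.unique(pooled).size == n + m, "oracle assumes no ties"
    ranks = np.arange(1, n + m + 1)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = [sum(cmb) - n * (n + 1) // 2 for cmb in combinations(ranks, n)]
    total = len(us)
    if alternative == "less":
        return sum(u <= u_obs for u in us) / total
    if alternative == "greater":
        return sum(u >= u_obs for u in us) / total
    p_less = sum(u <= u_obs for u in us) / total
    p_greater = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_less, p_greater))


def all_simple_paths_distance(edges: dict, a, b):
    """Shortest distance as min over all simple paths of summed 1/weight.

    ``edges`` maps frozenset({u, v}) -> weight.  Returns None when no path
    exists.  Pure DFS enumeration; exponential, for tiny graphs only.
    """
    adj: dict = {}
    for pair, w in edges.items():
        u, v = tuple(pair)
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    if a == b:
        return 0.0 if a in adj else None
    if a not in adj or b not in adj:
        return None
    best = [None]

    def dfs(node, visited, acc):
        if node == b:
            if best[0] is None or acc < best[0]:
                best[0] = acc
            return
        for nxt, w in adj.get(node, ()):
            if nxt not in visited:
                dfs(nxt, visited | {nxt}, acc + 1.0 / w)

    dfs(a, {a}, 0.0)
    return best[0]


def knn_oracle(points: np.ndarray, k: int):
    """Exhaustive k-nearest-neighbor search with (distance, index) ordering.

    Points must already be in lexicographic order; returns (lengths, angles)
    arrays matching the fan convention (angles in degrees, [0, 360)).
    """
    pts = np.asarray(points, float)
    n = pts.shape[0]
    lengths = np.empty((n, k))
    angles = np.empty((n, k))
    for i in range(n):
        cand = sorted(
            (float(np.hypot(*(pts[j] - pts[i]))), j) for j in range(n) if j != i
        )[:k]
        for slot, (dist, j) in enumerate(cand):
            dx, dy = pts[j] - pts[i]
            lengths[i, slot] = dist
            angles[i, slot] = np.degrees(np.arctan2(dy, dx)) % 360.0
    return lengths, angles


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct enumeration with math.comb arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def prob(x: int) -> float:
        return comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9)))
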