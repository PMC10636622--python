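"""Independent oracles used by the test suite.

These deliberately recompute quantities from first principles (full
enumeration, from-scratch sums of squares, closed forms) so that agreement
with the package is informative.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# Exact Mann-Whitney null distribution (no ties): counts of rank sums W1

@lru_cache(maxsize=None)
def ranksum_counts(n1: int, n: int) -> dict[int, int]:
    """Number of size-n1 subsets of ranks 1..n with each possible rank sum."""
    # DP over ranks; f[(k, s)] = number of ways to pick k ranks summing to s
    f = {(0, 0): 1}
    for r in range(1, n + 1):
        g = dict(f)
        for (k, s), c in f.items():
            if k < n1:
                g[(k + 1, s + r)] = g.get((k + 1, s + r), 0) + c
        f = g
    return {s: c for (k, s), c in f.items() if k == n1}


def exact_two_sided_p(w1: float, n1: int, n2: int) -> float:
    """Exact permutation two-sided p for rank sum w1 (distinct ranks)."""
    n = n1 + n2
    counts = ranksum_counts(n1, n)
    total = sum(counts.values())
    e = n1 * (n + 1) / 2.0
    dev = abs(w1 - e)
    tail = sum(c for s, c in counts.items() if abs(s - e) >= dev - 1e-9)
    return tail / total


# ---------------------------------------------------------------------------
# Brute-force Ward agglomeration: recompute ESS from scratch at every step

def _ess(x: np.ndarray) -> float:
    return float(((x - x.mean(axis=0)) ** 2).sum())


def brute_force_ward(x: np.ndarray, ids: list[str]) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
    """Merge sequence [(members_a, members_b, delta_ess), ...] by exhaustive
    ESS recomputation, with ties broken by smallest member ids."""
    clusters: list[tuple[tuple[str, ...], np.ndarray]] = [
        ((ids[i],), x[[i]]) for i in range(len(ids))
    ]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                (ma, xa), (mb, xb) = clusters[i], clusters[j]
                union = np.vstack([xa, xb])
                cost = _ess(union) - _ess(xa) - _ess(xb)
                key = (cost, tuple(sorted((min(ma), min(mb)))))
                if best is None or key < best[0]:
                    best = (key, i, j, cost)
        _, i, j, cost = best
        (ma, xa), (mb, xb) = clusters[i], clusters[j]
        merges.append((ma, mb, cost))
        merged = (tuple(sorted(ma + mb)), np.vstack([xa, xb]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


# ---------------------------------------------------------------------------
# Adjusted Rand index (closed form from the contingency table)

def adjusted_rand(truth, pred) -> float:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n = len(truth)
    tl, pl = np.unique(truth), np.unique(pred)
    ct = np.array([[np.sum((truth == t) & (pred == p)) for p in pl] for t in tl])

    def c2(v):
        v = np.asarray(v, dtype=float)
        return (v * (v - 1) / 2).sum()

    nij = c2(ct)
    a = c2(ct.sum(axis=1))
    b = c2(ct.sum(axis=0))
    expected = a * b / c2(np.array([n]))
    mx = 0.5 * (a + b)
    if mx == expected:
        return 1.0
    return (nij - expected) / (mx - expected)
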