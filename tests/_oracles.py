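"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def dtw_enumerate(x, y) -> float:
    """True exhaustive enumeration of all monotone warping paths.

    Exponential; only usable for short sequences. A path is a sequence of
    (i, j) cells from (0, 0) to (len(x)-1, len(y)-1) with steps in
    {(1,0), (0,1), (1,1)}; its cost is the sum of squared differences over
    its cells, and the distance is the square root of the minimal cost.
    """
    x = list(x)
    y = list(y)
    best = [math.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += (x[i] - y[j]) ** 2
        if cost >= best[0]:
            return
        if i == len(x) - 1 and j == len(y) - 1:
            best[0] = cost
            return
        if i + 1 < len(x) and j + 1 < len(y):
            walk(i + 1, j + 1, cost)
        if i + 1 < len(x):
            walk(i + 1, j, cost)
        if j + 1 < len(y):
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return math.sqrt(best[0])


def dtw_recursive(x, y) -> float:
    """Top-down memoized recursion on sequence prefixes (independent of the
    package's bottom-up array formulation)."""
    xt = tuple(float(v) for v in x)
    yt = tuple(float(v) for v in y)

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return math.inf
        cost = (xt[i] - yt[j]) ** 2
        if i == 0 and j == 0:
            return cost
        return cost + min(d(i - 1, j), d(i, j - 1), d(i - 1, j - 1))

    return math.sqrt(d(len(xt) - 1, len(yt) - 1))


def naive_hac(D: np.ndarray, linkage: str) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3)-ish list-based agglomerator recomputing inter-cluster distances
    from the original matrix at every step.

    Returns one (left leaves, right leaves, height) record per merge, ties
    broken by the smallest (min-leaf, min-leaf) pair, matching the
    convention that a merged cluster is indexed by its smallest leaf.
    """
    n = D.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pair_d = [D[i, j] for i in clusters[a] for j in clusters[b]]
                if linkage == "average":
                    dist = float(np.mean(pair_d))
                elif linkage == "complete":
                    dist = float(np.max(pair_d))
                else:
                    dist = float(np.min(pair_d))
                key = (dist, min(min(clusters[a]), min(clusters[b])),
                       max(min(clusters[a]), min(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dist, _, _), a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), dist))
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return merges


def linkage_to_merges(Z: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Expand a linkage matrix into (left leaves, right leaves, height)."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (left, right, height, _) in enumerate(Z):
        l, r = members[int(left)], members[int(right)]
        out.append((l, r, float(height)))
        members[n + step] = l | r
    return out


def silhouette_double_loop(D: np.ndarray, labels: np.ndarray) -> float:
    """Definitional mean silhouette on a precomputed distance matrix."""
    n = D.shape[0]
    vals = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == c])
            for c in np.unique(labels)
            if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def exact_shapley(f, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by full enumeration of feature orderings,
    averaging marginal contributions over every background row."""
    from itertools import permutations

    p = len(x)
    phi = np.zeros(p)
    count = 0
    for order in permutations(range(p)):
        for b in background:
            z = b.astype(float).copy()
            prev = float(f(z[None, :])[0])
            for j in order:
                z[j] = x[j]
                cur = float(f(z[None, :])[0])
                phi[j] += cur - prev
                prev = cur
        count += 1
    return phi / (count * len(background))
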