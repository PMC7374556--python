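"""Independent brute-force reference implementations for graph measures.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration — and shares no code with the package, so agreement is
evidence of correctness rather than of shared bugs.  Only usable on small
graphs (<= ~8 nodes for the exhaustive parts).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall_hops(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), math.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_oracle(a: np.ndarray) -> float:
    """Mean finite shortest-path length over ordered pairs i != j."""
    d = floyd_warshall_hops(a)
    vals = [d[i, j] for i in range(len(a)) for j in range(len(a))
            if i != j and math.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no finite pairs")
    return sum(vals) / len(vals)


def efficiency_oracle(a: np.ndarray) -> float:
    n = len(a)
    if n < 2:
        return 0.0
    d = floyd_warshall_hops(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_oracle(a: np.ndarray) -> float:
    n = len(a)
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        if len(nb) < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        total += efficiency_oracle(sub)
    return total / n


def clustering_oracle(a: np.ndarray) -> float:
    """Watts-Strogatz clustering by explicit triple enumeration."""
    n = len(a)
    cs = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            1 for u, v in itertools.combinations(nb, 2) if a[u, v]
        )
        cs.append(2.0 * links / (k * (k - 1)))
    return sum(cs) / n


def modularity_of_partition(a: np.ndarray, labels) -> float:
    """Newman-Girvan Q by the double-sum definition."""
    two_m = float(a.sum())
    k = a.sum(axis=1).astype(float)
    q = 0.0
    n = len(a)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(n: int):
    """All partitions of range(n) as label vectors (restricted growth strings)."""
    labels = [0] * n

    def rec(i, m):
        if i == n:
            yield tuple(labels)
            return
        for c in range(m + 1):
            labels[i] = c
            yield from rec(i + 1, max(m, c + 1))

    yield from rec(0, 0)


def max_modularity_oracle(a: np.ndarray) -> float:
    """Exhaustive search over all partitions; graphs of <= 8 nodes only."""
    n = len(a)
    assert n <= 8, "exhaustive search is only feasible for tiny graphs"
    return max(modularity_of_partition(a, labels) for labels in set_partitions(n))


def assortativity_oracle(a: np.ndarray) -> float:
    """Degree correlation over edge endpoints via the explicit sum formula."""
    deg = a.sum(axis=1).astype(float)
    pairs = []
    n = len(a)
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j]:
                pairs.append((deg[i], deg[j]))
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    mx, my = x.mean(), y.mean()
    denom = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    if denom == 0:
        raise ValueError("undefined")
    return float(((x - mx) * (y - my)).sum() / denom)


def betweenness_oracle(a: np.ndarray) -> np.ndarray:
    """Betweenness by enumerating ALL geodesics between every pair (DFS over
    paths of exactly the shortest length), normalized by (n-1)(n-2)/2."""
    n = len(a)
    d = floyd_warshall_hops(a)
    bc = np.zeros(n)

    def geodesics(s, t):
        target = d[s, t]
        if not math.isfinite(target):
            return []
        out = []

        def walk(path):
            last = path[-1]
            if last == t and len(path) - 1 == target:
                out.append(path)
                return
            if len(path) - 1 >= target:
                return
            for nxt in range(n):
                if a[last, nxt] and nxt not in path and \
                        d[nxt, t] == target - len(path):
                    walk(path + [nxt])

        walk([s])
        return out

    for s in range(n):
        for t in range(s + 1, n):
            paths = geodesics(s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    if n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation from the definitional sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def random_connected_adjacency(rng: np.random.Generator, n_max: int = 8) -> np.ndarray:
    """Random graph with 3..n_max nodes, redrawn until it has >= 1 edge."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.25, 0.9))
        a = (rng.random((n, n)) < p).astype(np.int8)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() >= 2:
            return a
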