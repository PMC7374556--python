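"""Graph-theory measures for thresholded group networks.

Global measures: average degree and strength, characteristic path length,
global and local efficiency, mean clustering coefficient, modularity (Q),
degree assortativity (r), and the small-worldness index (sigma).  Nodal
measure: shortest-path betweenness centrality.

All topology measures are computed on the BINARY thresholded graph; average
strength alone uses the retained correlation weights.  A weighted mode is
available for the distance- and clustering-based measures (edge length
1/w, Onnela clustering, weighted Q) but is not the default, since the
density-thresholding convention this package follows binarizes the graph
before topology is measured.

Conventions for disconnected graphs: node pairs with no connecting path are
excluded from the characteristic path length (their count is logged) and
contribute zero to efficiency.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import ThresholdedGraph

__all__ = [
    "MetricSet",
    "degree_and_strength",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "mean_clustering",
    "modularity",
    "assortativity",
    "small_worldness",
    "betweenness",
    "metric_set",
    "GLOBAL_MEASURES",
]

logger = logging.getLogger(__name__)

GLOBAL_MEASURES = (
    "average_degree",
    "average_strength",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "mean_clustering",
    "modularity",
    "assortativity",
    "small_worldness",
)


@dataclass
class MetricSet:
    """The nine global measures plus per-node betweenness for one graph."""

    average_degree: float
    average_strength: float
    characteristic_path_length: float
    global_efficiency: float
    local_efficiency: float
    mean_clustering: float
    modularity: float
    assortativity: float
    small_worldness: float
    betweenness: np.ndarray

    def as_dict(self) -> dict:
        d = asdict(self)
        d["betweenness"] = np.asarray(self.betweenness).tolist()
        return d


# --------------------------------------------------------------------- #
# internal routines on plain adjacency / weight arrays (hot path)


def _distance_matrix(a: np.ndarray, lengths: np.ndarray | None = None) -> np.ndarray:
    if lengths is None:
        return shortest_path(csr_matrix(a), method="D", unweighted=True)
    return shortest_path(csr_matrix(lengths), method="D")


def _path_length(dist: np.ndarray) -> tuple[float, int]:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    finite = np.isfinite(d)
    n_inf = int((~finite).sum())
    if finite.sum() == 0:
        raise ValueError("no finite pairwise paths; path length undefined")
    return float(d[finite].mean()), n_inf


def _efficiency(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def _local_efficiency(a: np.ndarray, lengths: np.ndarray | None = None) -> float:
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub_len = None if lengths is None else lengths[np.ix_(nb, nb)]
        total += _efficiency(_distance_matrix(a[np.ix_(nb, nb)], sub_len))
    return total / n


def _clustering_mean(a: np.ndarray) -> float:
    af = a.astype(float)
    k = af.sum(axis=1)
    tri2 = np.diag(af @ af @ af)  # 2x triangle count per node
    denom = k * (k - 1)
    c = np.divide(tri2, denom, out=np.zeros_like(tri2), where=denom > 0)
    return float(c.mean())


def _onnela_clustering_mean(w: np.ndarray) -> float:
    wmax = w.max()
    if wmax <= 0:
        return 0.0
    what = np.cbrt(w / wmax)
    k = (w > 0).sum(axis=1).astype(float)
    tri = np.diag(what @ what @ what)
    denom = k * (k - 1)
    c = np.divide(tri, denom, out=np.zeros_like(tri), where=denom > 0)
    return float(c.mean())


def _newman_q(a: np.ndarray, membership: np.ndarray) -> float:
    """Newman-Girvan modularity of a partition on a (possibly weighted)
    symmetric nonnegative matrix with zero diagonal."""
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    deg = a.sum(axis=1)
    q = 0.0
    for c in np.unique(membership):
        idx = membership == c
        q += a[np.ix_(idx, idx)].sum() / two_m - (deg[idx].sum() / two_m) ** 2
    return float(q)


_EXACT_Q_MAX_NODES = 12


def _best_partition_q(
    a: np.ndarray, seed: int, restarts: int, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Best community partition, scored by our own Newman-Girvan Q.

    Graphs of up to 12 nodes are solved by exact modularity optimization
    (integer programming), where it is instantaneous; larger graphs use
    Louvain with ``restarts`` seeded restarts, keeping the best Q.  Louvain
    is a greedy heuristic and can miss the optimum on tiny graphs, so exact
    search where feasible both removes that failure mode and removes the
    seed dependence.  Partition search is delegated to igraph (Louvain is
    seeded through Python's random module, whose state is saved and
    restored); the modularity value itself is always recomputed with
    :func:`_newman_q`.
    """
    import igraph as ig

    mat = a if weights is None else weights
    if mat.sum() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    src, dst = np.nonzero(np.triu(mat, k=1))
    g = ig.Graph(n=a.shape[0], edges=list(zip(src.tolist(), dst.tolist())))
    edge_w = mat[src, dst].tolist() if weights is not None else None

    if a.shape[0] <= _EXACT_Q_MAX_NODES:
        clusters = g.community_optimal_modularity(weights=edge_w)
        member = np.asarray(clusters.membership)
        return max(_newman_q(mat, member), 0.0), member

    ss = np.random.SeedSequence(seed)
    subseeds = ss.generate_state(restarts)
    best_q, best_membership = -np.inf, None
    state = _pyrandom.getstate()
    try:
        for sub in subseeds:
            _pyrandom.seed(int(sub))
            clusters = g.community_multilevel(weights=edge_w)
            member = np.asarray(clusters.membership)
            q = _newman_q(mat, member)
            if q > best_q:
                best_q, best_membership = q, member
    finally:
        _pyrandom.setstate(state)
    # a single community always achieves Q = 0; never report worse
    if best_q < 0.0:
        best_q, best_membership = 0.0, np.zeros(a.shape[0], dtype=int)
    return best_q, best_membership


def _degree_assortativity(a: np.ndarray) -> float:
    deg = a.sum(axis=1).astype(float)
    src, dst = np.nonzero(np.triu(a, k=1))
    if src.size < 2:
        raise ValueError("assortativity needs at least 2 edges")
    x = np.concatenate([deg[src], deg[dst]])
    y = np.concatenate([deg[dst], deg[src]])
    if np.ptp(x) == 0:
        raise ValueError("assortativity undefined: zero degree variance at endpoints")
    return float(np.corrcoef(x, y)[0, 1])


def _rewire_degree_preserving(
    a: np.ndarray, rng: np.random.Generator, attempts_per_edge: int
) -> tuple[np.ndarray, int]:
    """Degree-preserving double-edge swaps; returns (adjacency, n_swapped)."""
    src, dst = np.nonzero(np.triu(a, k=1))
    edges = list(zip(src.tolist(), dst.tolist()))
    edge_set = set(edges)
    n_edges = len(edges)
    if n_edges < 2:
        return a.copy(), 0
    n_attempts = attempts_per_edge * n_edges
    picks = rng.integers(0, n_edges, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    swapped = 0
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a1, b1 = edges[e1]
        c1, d1 = edges[e2]
        if flip:
            c1, d1 = d1, c1
        # proposed new edges (a1,d1) and (c1,b1)
        if len({a1, b1, c1, d1}) < 4:
            continue
        new1 = (min(a1, d1), max(a1, d1))
        new2 = (min(c1, b1), max(c1, b1))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1], edges[e2] = new1, new2
        swapped += 1
    out = np.zeros_like(a)
    if edges:
        es, ed = zip(*edges)
        out[list(es), list(ed)] = 1
        out |= out.T
    return out, swapped


def _random_same_size(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi G(n, m) with the same node and edge count."""
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    m = int(a.sum() // 2)
    keep = rng.choice(iu.size, size=m, replace=False)
    out = np.zeros_like(a)
    out[iu[keep], ju[keep]] = 1
    out |= out.T
    return out


# --------------------------------------------------------------------- #
# public operations on ThresholdedGraph


def _adj(g: ThresholdedGraph) -> np.ndarray:
    return np.asarray(g.adjacency, dtype=np.int8)


def _lengths(g: ThresholdedGraph, weighted: bool) -> np.ndarray | None:
    """Edge length matrix 1/w for weighted distances, else None (hop count)."""
    if not weighted:
        return None
    w = g.retained_weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return lengths


def degree_and_strength(g: ThresholdedGraph) -> tuple[float, float]:
    """Average binary degree and average retained-weight strength."""
    a = _adj(g)
    avg_degree = float(a.sum(axis=1).mean())
    avg_strength = float(g.retained_weights.sum(axis=1).mean())
    return avg_degree, avg_strength


def characteristic_path_length(g: ThresholdedGraph, weighted: bool = False) -> float:
    dist = _distance_matrix(_adj(g), _lengths(g, weighted))
    value, n_inf = _path_length(dist)
    if n_inf:
        logger.info("%d disconnected ordered pairs excluded from path length", n_inf)
    return value


def global_efficiency(g: ThresholdedGraph, weighted: bool = False) -> float:
    return _efficiency(_distance_matrix(_adj(g), _lengths(g, weighted)))


def local_efficiency(g: ThresholdedGraph, weighted: bool = False) -> float:
    return _local_efficiency(_adj(g), _lengths(g, weighted))


def mean_clustering(g: ThresholdedGraph, weighted: bool = False) -> float:
    if weighted:
        return _onnela_clustering_mean(g.retained_weights)
    return _clustering_mean(_adj(g))


def modularity(
    g: ThresholdedGraph,
    seed: int = 0,
    restarts: int = 10,
    weighted: bool = False,
) -> tuple[float, np.ndarray]:
    """Best Newman-Girvan Q over seeded Louvain restarts, with its partition."""
    a = _adj(g).astype(float)
    weights = g.retained_weights if weighted else None
    return _best_partition_q(a, seed, restarts, weights)


def assortativity(g: ThresholdedGraph) -> float:
    """Newman degree assortativity: Pearson correlation of endpoint degrees."""
    return _degree_assortativity(_adj(g))


def small_worldness(
    g: ThresholdedGraph,
    n_null: int = 20,
    seed: int = 0,
    rewire_attempts_per_edge: int = 10,
    weighted: bool = False,
) -> float:
    """sigma = (C/C_null) / (L/L_null) against degree-preserving rewired nulls.

    Each null performs ``rewire_attempts_per_edge * E`` swap attempts.  If a
    null cannot be rewired at all (no successful swap despite attempts), an
    Erdos-Renyi graph with the same node and edge count is used instead and
    the fallback is logged.  ``rewire_attempts_per_edge=0`` deliberately
    compares the graph against itself (sigma = 1), a degenerate setting used
    for validation.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    a = _adj(g)
    lengths = _lengths(g, weighted)
    c_obs = (
        _onnela_clustering_mean(g.retained_weights) if weighted else _clustering_mean(a)
    )
    l_obs, _ = _path_length(_distance_matrix(a, lengths))
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        null_a, n_swapped = _rewire_degree_preserving(a, rng, rewire_attempts_per_edge)
        if rewire_attempts_per_edge > 0 and n_swapped == 0:
            logger.warning(
                "degree-preserving rewiring failed; falling back to Erdos-Renyi null"
            )
            null_a = _random_same_size(a, rng)
        null_lengths = None
        if weighted:
            # carry observed weights onto the rewired topology in sorted order
            null_lengths = _assign_weights_like(null_a, g.retained_weights)
            c_null.append(_onnela_clustering_mean(1.0 / np.where(null_lengths > 0, null_lengths, np.inf)))
        else:
            c_null.append(_clustering_mean(null_a))
        l_val, _ = _path_length(_distance_matrix(null_a, null_lengths))
        l_null.append(l_val)
    c_bar, l_bar = float(np.mean(c_null)), float(np.mean(l_null))
    if c_bar <= 0 or l_bar <= 0:
        raise ValueError("null graphs give zero clustering or path length")
    return (c_obs / c_bar) / (l_obs / l_bar)


def _assign_weights_like(null_a: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Edge lengths 1/w for a null topology reusing the observed weight
    multiset (descending weight onto arbitrary edge order)."""
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w_vals = np.sort(weights[iu, ju])[::-1]
    src, dst = np.nonzero(np.triu(null_a, k=1))
    lengths = np.zeros_like(weights)
    use = w_vals[: src.size]
    lengths[src, dst] = 1.0 / use
    lengths += lengths.T
    return lengths


def betweenness(g: ThresholdedGraph) -> np.ndarray:
    """Brandes shortest-path betweenness on the binary graph, normalized by
    (R-1)(R-2)/2 so entries lie in [0, 1]."""
    graph = nx.from_numpy_array(_adj(g))
    bc = nx.betweenness_centrality(graph, normalized=True)
    return np.array([bc[i] for i in range(g.n_nodes)])


def metric_set(
    g: ThresholdedGraph,
    seed: int = 0,
    n_null_sigma: int = 20,
    modularity_restarts: int = 10,
    weighted: bool = False,
) -> MetricSet:
    """All global measures plus nodal betweenness, one seed governing the
    modularity restarts and small-worldness nulls."""
    ss = np.random.SeedSequence(seed)
    seed_q, seed_sigma = (int(s) for s in ss.generate_state(2))
    avg_deg, avg_str = degree_and_strength(g)
    q, _ = modularity(g, seed=seed_q, restarts=modularity_restarts, weighted=weighted)
    # assortativity and sigma are undefined on some degenerate graphs
    # (regular degree sequence; nulls with zero clustering); the aggregated
    # set reports NaN for them rather than failing the remaining measures
    try:
        r = assortativity(g)
    except ValueError as exc:
        logger.info("assortativity undefined: %s", exc)
        r = float("nan")
    try:
        sigma = small_worldness(
            g, n_null=n_null_sigma, seed=seed_sigma, weighted=weighted
        )
    except ValueError as exc:
        logger.info("small-worldness undefined: %s", exc)
        sigma = float("nan")
    return MetricSet(
        average_degree=avg_deg,
        average_strength=avg_str,
        characteristic_path_length=characteristic_path_length(g, weighted),
        global_efficiency=global_efficiency(g, weighted),
        local_efficiency=local_efficiency(g, weighted),
        mean_clustering=mean_clustering(g, weighted),
        modularity=q,
        assortativity=r,
        small_worldness=sigma,
        betweenness=betweenness(g),
    )
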