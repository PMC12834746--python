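"""Binary brain graphs and their topological metrics.

A group-level connectivity matrix is binarized by keeping, at a given
*sparsity* ``s``, the ``K = round_half_up(s * n_pairs)`` node pairs with the
largest (signed) correlation, yielding an undirected, unweighted graph with
no self-loops.  The study sweeps sparsity 0.10-0.50 in steps of 0.01 and
summarizes each metric curve by its area under the sparsity curve (AUC).

Global metrics: clustering coefficient Cp, characteristic path length Lp,
global efficiency Eglob, local efficiency Eloc, and the small-world indices
gamma = Cp / <Cp_rand>, lambda = Lp / <Lp_rand>, sigma = gamma / lambda,
where the random reference is an ensemble of Maslov-Sneppen degree-preserving
rewirings of the observed graph.  Nodal metrics: degree, betweenness
(Brandes convention, undirected, unnormalized), and nodal efficiency.

Everything here operates on dense 0/1 adjacency matrices with vectorized
numpy kernels (all-pairs BFS via boolean matrix products) because the
permutation machinery upstream re-evaluates on the order of 10^5-10^6 graphs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryGraph",
    "GlobalMetrics",
    "NodalMetrics",
    "round_half_up",
    "edge_ranking",
    "threshold_by_sparsity",
    "sparsity_sweep",
    "bfs_distances",
    "global_graph_metrics",
    "nodal_graph_metrics",
    "betweenness_centrality",
    "rewire_preserving_degree",
    "small_world_metrics",
    "auc_over_sparsity",
    "DEFAULT_SPARSITIES",
]

#: Sparsity grid 0.10-0.50, step 0.01 (41 points).
DEFAULT_SPARSITIES: np.ndarray = np.round(np.arange(0.10, 0.50 + 1e-9, 0.01), 2)


class DegenerateThresholdError(ValueError):
    """Sparsity so low that no edge survives thresholding."""


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero-half upward (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected unweighted graph as a dense symmetric 0/1 adjacency."""

    adjacency: np.ndarray
    sparsity: float | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        object.__setattr__(self, "adjacency", a.astype(bool))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GlobalMetrics:
    """Global topology summaries, optionally with small-world normalization."""

    Cp: float
    Lp: float
    Eglob: float
    Eloc: float
    gamma: float | None = None
    lam: float | None = None
    sigma: float | None = None


@dataclass
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    efficiency: np.ndarray


def edge_ranking(r: np.ndarray, use_abs: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Candidate edges (upper triangle) ranked by descending correlation.

    Ties are broken lexicographically by (i, j) for cross-platform
    determinism.  By default the signed correlation is ranked (positive
    coupling networks); ``use_abs`` switches to magnitude ranking.

    Returns (ii, jj) index arrays of length n*(n-1)/2, strongest edge first.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    vals = np.abs(r[ii, jj]) if use_abs else r[ii, jj]
    # lexsort: last key is primary
    order = np.lexsort((jj, ii, -vals))
    return ii[order], jj[order]


def threshold_by_sparsity(
    r: np.ndarray, sparsity: float, use_abs: bool = False
) -> BinaryGraph:
    """Binarize a correlation matrix at a target edge density.

    Keeps the ``K = round_half_up(sparsity * n_pairs)`` strongest edges.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if not 0.0 < sparsity < 1.0:
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    n_pairs = n * (n - 1) // 2
    k = round_half_up(sparsity * n_pairs)
    if k == 0:
        raise DegenerateThresholdError(
            f"sparsity {sparsity} keeps 0 of {n_pairs} edges"
        )
    ii, jj = edge_ranking(r, use_abs=use_abs)
    a = np.zeros((n, n), dtype=bool)
    a[ii[:k], jj[:k]] = True
    a |= a.T
    return BinaryGraph(a, sparsity=float(sparsity))


def sparsity_sweep(r: np.ndarray, sparsities: np.ndarray, use_abs: bool = False):
    """Yield ``(sparsity, adjacency)`` over an increasing sparsity grid.

    The graphs are nested: each is the previous plus the next-ranked edges,
    built incrementally so a 41-point sweep costs one sort.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    n_pairs = n * (n - 1) // 2
    ii, jj = edge_ranking(r, use_abs=use_abs)
    a = np.zeros((n, n), dtype=bool)
    prev_k = 0
    for s in np.asarray(sparsities, dtype=float):
        k = round_half_up(s * n_pairs)
        if k == 0:
            raise DegenerateThresholdError(f"sparsity {s} keeps 0 edges")
        if k < prev_k:
            raise ValueError("sparsities must be non-decreasing")
        sel = slice(prev_k, k)
        a[ii[sel], jj[sel]] = True
        a[jj[sel], ii[sel]] = True
        prev_k = k
        yield float(s), a


def batched_bfs_distances(stack: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths for a stack of binary graphs at once.

    ``stack`` has shape (m, n, n); the BFS is level-synchronous over the
    whole stack via boolean stacked matrix products.  Returns (m, n, n)
    distances with ``inf`` for unreachable pairs.
    """
    stack = np.asarray(stack, dtype=bool)
    m, n, _ = stack.shape
    stack_f = stack.astype(np.float32)  # float matmul hits BLAS; bool does not
    dist = np.full((m, n, n), np.inf)
    eye = np.eye(n, dtype=bool)
    dist[:, eye] = 0.0
    reached = np.broadcast_to(eye, (m, n, n)).copy()
    frontier = reached.copy()
    d = 0
    while True:
        frontier = ((frontier.astype(np.float32) @ stack_f) > 0) & ~reached
        if not frontier.any():
            break
        d += 1
        dist[frontier] = d
        reached |= frontier
    return dist


def batched_global_metrics(stack: np.ndarray, chunk: int = 512) -> dict[str, np.ndarray]:
    """Cp, Lp, Eglob, Eloc for a stack of graphs in one vectorized pass.

    Shares the conventions of :func:`global_graph_metrics`; used by the
    permutation machinery, which evaluates tens of thousands of sparsity
    sweeps.  ``chunk`` bounds the memory of the local-efficiency BFS
    (one subgraph per node per graph).
    """
    stack = np.asarray(stack, dtype=bool)
    m, n, _ = stack.shape
    af = stack.astype(np.float64)
    deg = af.sum(axis=2)                                    # (m, n)
    tri2 = np.einsum("mij,mjk,mki->mi", af, af, af)
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cp = np.where(denom > 0, tri2 / denom, 0.0).mean(axis=1)

    dist = batched_bfs_distances(stack)
    eye = np.eye(n, dtype=bool)
    finite_off = np.isfinite(dist) & ~eye
    lp_sum = np.where(finite_off, dist, 0.0).sum(axis=(1, 2))
    lp_cnt = finite_off.sum(axis=(1, 2))
    with np.errstate(invalid="ignore"):
        lp = np.where(lp_cnt > 0, lp_sum / lp_cnt, 0.0)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[:, eye] = 0.0
    eglob = inv.sum(axis=(1, 2)) / (n * (n - 1))

    # local efficiency: one neighbor-induced subgraph per (graph, node)
    k = deg.astype(int).reshape(m * n)
    eloc_node = np.zeros(m * n)
    if n <= 20:
        # small graphs: one full-size masked stack beats bucketing overhead
        masks = stack[:, :, None, :] & stack[:, :, :, None]
        subs_all = (masks & stack[:, None, :, :]).reshape(m * n, n, n)
        pair_mask = masks.reshape(m * n, n, n)
        sel = np.flatnonzero(k >= 2)
        for start in range(0, sel.size, chunk):
            part = sel[start:start + chunk]
            d_sub = batched_bfs_distances(subs_all[part])
            with np.errstate(divide="ignore"):
                inv_sub = 1.0 / d_sub
            inv_sub[~np.isfinite(d_sub)] = 0.0
            inv_sub[:, np.eye(n, dtype=bool)] = 0.0
            inv_sub[~pair_mask[part]] = 0.0
            eloc_node[part] = inv_sub.sum(axis=(1, 2)) / (k[part] * (k[part] - 1))
        eloc = eloc_node.reshape(m, n).mean(axis=1)
        return {"Cp": cp, "Lp": lp, "Eglob": eglob, "Eloc": eloc}
    # larger graphs: bucket by subgraph size so BFS runs on k x k matrices
    buckets: dict[int, list[int]] = {}
    for idx in np.flatnonzero(k >= 2):
        buckets.setdefault(int(k[idx]), []).append(idx)
    for size, idxs in buckets.items():
        for start in range(0, len(idxs), chunk):
            part = idxs[start:start + chunk]
            subs = np.empty((len(part), size, size), dtype=bool)
            for t, idx in enumerate(part):
                g, i = divmod(idx, n)
                nbrs = np.flatnonzero(stack[g, i])
                subs[t] = stack[g][np.ix_(nbrs, nbrs)]
            d_sub = batched_bfs_distances(subs)
            with np.errstate(divide="ignore"):
                inv_sub = 1.0 / d_sub
            inv_sub[~np.isfinite(d_sub)] = 0.0
            inv_sub[:, np.eye(size, dtype=bool)] = 0.0
            eloc_node[part] = inv_sub.sum(axis=(1, 2)) / (size * (size - 1))
    eloc = eloc_node.reshape(m, n).mean(axis=1)
    return {"Cp": cp, "Lp": lp, "Eglob": eglob, "Eloc": eloc}


def bfs_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of a binary graph.

    Level-synchronous BFS from all sources at once, using boolean matrix
    products; unreachable pairs get ``inf``.
    """
    a = np.asarray(a, dtype=bool)
    n = a.shape[0]
    a_f = a.astype(np.float32)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    d = 0
    while True:
        frontier = ((frontier.astype(np.float32) @ a_f) > 0) & ~reached
        if not frontier.any():
            break
        d += 1
        dist[frontier] = d
        reached |= frontier
    return dist


def _clustering_per_node(a: np.ndarray) -> np.ndarray:
    af = a.astype(np.float64)
    deg = af.sum(axis=1)
    # diag(A^3) counts 2 * triangles through each node
    tri2 = np.einsum("ij,jk,ki->i", af, af, af)
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def _pairwise_efficiency(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_graph_metrics(g: BinaryGraph | np.ndarray) -> GlobalMetrics:
    """Cp, Lp, Eglob, Eloc of a binary graph.

    Lp averages over *connected* ordered pairs only (the common toolbox
    convention for graphs that fragment at low sparsity); Eglob uses
    1/inf = 0 so disconnection is penalized there instead.  Nodes of degree
    < 2 contribute 0 to both Cp and Eloc.
    """
    a = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g, dtype=bool)
    n = a.shape[0]
    if a.sum() == 0:
        warnings.warn("empty graph: all global metrics set to 0", stacklevel=2)
        return GlobalMetrics(0.0, 0.0, 0.0, 0.0)

    cp = float(_clustering_per_node(a).mean())

    dist = bfs_distances(a)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    lp = float(dist[finite].mean()) if finite.any() else 0.0
    eglob = _pairwise_efficiency(dist)

    eloc_terms = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        eloc_terms[i] = _pairwise_efficiency(bfs_distances(sub))
    eloc = float(eloc_terms.mean())
    return GlobalMetrics(cp, lp, eglob, eloc)


def betweenness_centrality(a: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness, Brandes accumulation, undirected graphs.

    Each unordered pair {s, t} contributes 1 in total, split fractionally
    over the shortest s-t paths.
    """
    a = np.asarray(a, dtype=bool)
    n = a.shape[0]
    adj = [np.flatnonzero(a[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source BFS with path counting
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        order: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        queue = [s]
        while queue:
            nxt: list[int] = []
            for v in queue:
                order.append(v)
                for w in adj[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            queue = nxt
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each pair counted from both endpoints


def nodal_graph_metrics(g: BinaryGraph | np.ndarray) -> NodalMetrics:
    """Degree, betweenness, and nodal efficiency per node."""
    a = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g, dtype=bool)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    degree = a.sum(axis=1).astype(int)
    dist = bfs_distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    efficiency = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(degree, betweenness_centrality(a), efficiency)


def rewire_preserving_degree(
    g: BinaryGraph | np.ndarray,
    n_swaps: int | None = None,
    rng: np.random.Generator | int | None = None,
    max_attempt_factor: int = 100,
) -> np.ndarray:
    """Maslov-Sneppen double-edge-swap randomization.

    Repeatedly picks two edges (a-b, c-d) and rewires them to (a-d, c-b)
    when no self-loop or multi-edge results, preserving every node's degree
    exactly.  ``n_swaps`` defaults to 10x the edge count.  If the attempt
    budget (``max_attempt_factor * n_swaps``) is exhausted before all swaps
    succeed -- e.g. for a complete graph, which admits no legal swap -- the
    best-effort graph is returned with a warning.
    """
    a = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g, dtype=bool)
    a = a.copy()
    rng = np.random.default_rng(rng)
    ii, jj = np.nonzero(np.triu(a, k=1))
    m = ii.size
    if m < 2:
        return a
    edges = np.stack([ii, jj], axis=1)
    if n_swaps is None:
        n_swaps = 10 * m
    swaps_done = 0
    attempts = 0
    budget = max(1, max_attempt_factor * n_swaps)
    while swaps_done < n_swaps and attempts < budget:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        x1, y1 = edges[e1]
        x2, y2 = edges[e2]
        if rng.random() < 0.5:
            x2, y2 = y2, x2
        # propose x1-x2, y1-y2
        if x1 == x2 or y1 == y2:
            continue
        if a[x1, x2] or a[y1, y2]:
            continue
        a[x1, y1] = a[y1, x1] = False
        a[x2, y2] = a[y2, x2] = False
        a[x1, x2] = a[x2, x1] = True
        a[y1, y2] = a[y2, y1] = True
        edges[e1] = sorted((x1, x2))
        edges[e2] = sorted((y1, y2))
        swaps_done += 1
    if swaps_done < n_swaps and attempts >= budget:
        warnings.warn(
            f"rewiring attempt budget exhausted after {swaps_done}/{n_swaps} "
            "swaps; returning best-effort graph",
            stacklevel=2,
        )
    return a


class DegenerateNullError(ValueError):
    """Null ensemble produced a zero mean Cp or Lp."""


def small_world_metrics(
    g: BinaryGraph | np.ndarray,
    n_null: int = 100,
    rng: np.random.Generator | int | None = None,
    n_swaps: int | None = None,
) -> tuple[float, float, float]:
    """Small-world indices (gamma, lambda, sigma) against rewired nulls.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma / lambda,
    with the null ensemble of ``n_null`` degree-preserving rewirings.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    a = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g, dtype=bool)
    rng = np.random.default_rng(rng)

    def cp_lp(adj):
        cp = float(_clustering_per_node(adj).mean())
        dist = bfs_distances(adj)
        finite = np.isfinite(dist) & ~np.eye(adj.shape[0], dtype=bool)
        lp = float(dist[finite].mean()) if finite.any() else 0.0
        return cp, lp

    obs_cp, obs_lp = cp_lp(a)
    null_cp = np.empty(n_null)
    null_lp = np.empty(n_null)
    for k in range(n_null):
        null = rewire_preserving_degree(a, n_swaps=n_swaps, rng=rng)
        null_cp[k], null_lp[k] = cp_lp(null)
    mean_cp = null_cp.mean()
    mean_lp = null_lp.mean()
    if mean_cp == 0 or mean_lp == 0:
        raise DegenerateNullError("null ensemble has zero mean Cp or Lp")
    gamma = obs_cp / mean_cp
    lam = obs_lp / mean_lp
    return float(gamma), float(lam), float(gamma / lam)


def auc_over_sparsity(values, sparsities) -> float:
    """Trapezoidal area under a metric curve over the sparsity grid."""
    values = np.asarray(values, dtype=float)
    sparsities = np.asarray(sparsities, dtype=float)
    if values.shape != sparsities.shape:
        raise ValueError("values and sparsities must have equal length")
    if sparsities.size < 2:
        raise ValueError("need at least 2 grid points")
    if np.any(np.diff(sparsities) <= 0):
        raise ValueError("sparsities must be strictly increasing")
    return float(np.trapezoid(values, sparsities))
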