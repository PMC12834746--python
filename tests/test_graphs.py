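"""Binary graph construction and topological metrics vs brute-force oracles."""

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from metconn.graphs import (
    BinaryGraph,
    DegenerateThresholdError,
    auc_over_sparsity,
    batched_global_metrics,
    bfs_distances,
    global_graph_metrics,
    nodal_graph_metrics,
    rewire_preserving_degree,
    round_half_up,
    small_world_metrics,
    sparsity_sweep,
    threshold_by_sparsity,
)
from conftest import random_graph


# ---------------------------------------------------------------- oracles
def oracle_bfs(a, src):
    n = a.shape[0]
    dist = np.full(n, np.inf)
    dist[src] = 0
    q = deque([src])
    while q:
        v = q.popleft()
        for w in np.flatnonzero(a[v]):
            if dist[w] == np.inf:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def oracle_metrics(a):
    """Triangle enumeration + per-source BFS, deliberately naive."""
    n = a.shape[0]
    # clustering
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(a[u, v] for u, v in combinations(nbrs, 2))
        cs.append(2.0 * links / (k * (k - 1)))
    cp = float(np.mean(cs))
    dist = np.array([oracle_bfs(a, s) for s in range(n)])
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    lp = float(dist[finite].mean()) if finite.any() else 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[np.eye(n, dtype=bool)] = 0.0
    eglob = float(inv.sum() / (n * (n - 1)))
    elocs = []
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            elocs.append(0.0)
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        k = nbrs.size
        dsub = np.array([oracle_bfs(sub, s) for s in range(k)])
        with np.errstate(divide="ignore"):
            isub = 1.0 / dsub
        isub[np.eye(k, dtype=bool)] = 0.0
        elocs.append(float(isub.sum() / (k * (k - 1))))
    eloc = float(np.mean(elocs))
    nodal_eff = inv.sum(axis=1) / (n - 1)
    return cp, lp, eglob, eloc, dist, nodal_eff


def oracle_betweenness(a):
    """Brandes by explicit shortest-path enumeration (networkx paths)."""
    g = nx.from_numpy_array(np.asarray(a, dtype=int))
    n = a.shape[0]
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


# ---------------------------------------------------------------- threshold
class TestThresholdBySparsity:
    def test_four_node_half_sparsity(self, rng):
        r = np.corrcoef(rng.normal(size=(8, 4)), rowvar=False)
        g = threshold_by_sparsity(r, 0.5)
        assert g.n_edges == 3
        iu = np.triu_indices(4, 1)
        kept = r[iu][g.adjacency[iu]]
        assert set(np.round(kept, 12)) == set(np.round(np.sort(r[iu])[-3:], 12))

    def test_round_half_up_edge_count(self, rng):
        r = np.corrcoef(rng.normal(size=(30, 90)), rowvar=False)
        g = threshold_by_sparsity(r, 0.10)
        assert g.n_edges == 401  # 0.10 * 4005 = 400.5, half-up

    def test_lexicographic_tie_break(self):
        r = np.full((5, 5), 0.5)
        np.fill_diagonal(r, 1.0)
        g = threshold_by_sparsity(r, 0.3)  # K = 3 of 10
        ii, jj = np.nonzero(np.triu(g.adjacency, 1))
        assert list(zip(ii, jj)) == [(0, 1), (0, 2), (0, 3)]

    def test_degenerate_threshold_raises(self):
        with pytest.raises(DegenerateThresholdError):
            threshold_by_sparsity(np.eye(4), 0.01)

    def test_sweep_invariants(self, rng):
        r = np.corrcoef(rng.normal(size=(20, 30)), rowvar=False)
        grid = np.arange(0.10, 0.51, 0.05)
        n_pairs = 30 * 29 // 2
        prev = 0
        for s, a in sparsity_sweep(r, grid):
            assert np.array_equal(a, a.T)
            assert not a.diagonal().any()
            k = int(a.sum()) // 2
            assert k == round_half_up(s * n_pairs)
            assert k >= prev
            prev = k


# ---------------------------------------------------------------- metrics
class TestGlobalMetrics:
    def test_complete_k4(self):
        a = ~np.eye(4, dtype=bool)
        gm = global_graph_metrics(a)
        assert (gm.Cp, gm.Lp, gm.Eglob, gm.Eloc) == (1.0, 1.0, 1.0, 1.0)

    def test_path_p4(self):
        a = np.zeros((4, 4), dtype=bool)
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = True
        gm = global_graph_metrics(a)
        assert gm.Cp == 0.0
        assert gm.Lp == pytest.approx(10 / 6)
        assert gm.Eglob == pytest.approx(13 / 18)

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            a = random_graph(rng, n, p=rng.uniform(0.2, 0.7))
            gm = global_graph_metrics(a)
            cp, lp, eglob, eloc, dist, _ = oracle_metrics(a)
            assert gm.Cp == pytest.approx(cp, abs=1e-12)
            assert gm.Lp == pytest.approx(lp, abs=1e-12)
            assert gm.Eglob == pytest.approx(eglob, abs=1e-12)
            assert gm.Eloc == pytest.approx(eloc, abs=1e-12)
            assert np.array_equal(bfs_distances(a), dist)

    def test_batched_equals_single(self):
        rng = np.random.default_rng(5)
        stack = np.array([random_graph(rng, 11, 0.4) for _ in range(25)])
        batch = batched_global_metrics(stack)
        for k, a in enumerate(stack):
            gm = global_graph_metrics(a)
            assert batch["Cp"][k] == pytest.approx(gm.Cp, abs=1e-12)
            assert batch["Lp"][k] == pytest.approx(gm.Lp, abs=1e-12)
            assert batch["Eglob"][k] == pytest.approx(gm.Eglob, abs=1e-12)
            assert batch["Eloc"][k] == pytest.approx(gm.Eloc, abs=1e-12)

    def test_empty_graph_warns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            gm = global_graph_metrics(np.zeros((4, 4), dtype=bool))
        assert (gm.Cp, gm.Lp, gm.Eglob, gm.Eloc) == (0, 0, 0, 0)

    def test_eglob_at_least_inverse_lp_when_connected(self):
        # Jensen: mean(1/d) >= 1/mean(d)
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 20:
            a = random_graph(rng, 10, 0.35)
            if not np.isfinite(bfs_distances(a)).all():
                continue
            gm = global_graph_metrics(a)
            assert gm.Eglob >= 1.0 / gm.Lp - 1e-12
            checked += 1

    def test_eglob_monotone_over_nested_sweep(self, rng):
        r = np.corrcoef(rng.normal(size=(15, 20)), rowvar=False)
        vals = [global_graph_metrics(a).Eglob
                for _, a in sparsity_sweep(r, np.arange(0.1, 0.55, 0.05))]
        assert (np.diff(vals) >= -1e-12).all()


class TestNodalMetrics:
    def test_star_graph(self):
        a = np.zeros((5, 5), dtype=bool)
        a[0, 1:] = a[1:, 0] = True
        nm = nodal_graph_metrics(a)
        assert nm.degree.tolist() == [4, 1, 1, 1, 1]
        assert nm.betweenness[0] == pytest.approx(6.0)
        assert np.allclose(nm.betweenness[1:], 0.0)
        assert nm.efficiency[0] == pytest.approx(1.0)
        assert np.allclose(nm.efficiency[1:], 0.625)

    def test_p3_middle_betweenness(self):
        a = np.zeros((3, 3), dtype=bool)
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = True
        assert nodal_graph_metrics(a).betweenness[1] == pytest.approx(1.0)

    def test_degree_sum_is_twice_edges(self, rng):
        a = random_graph(rng, 15, 0.3)
        nm = nodal_graph_metrics(a)
        assert nm.degree.sum() == int(a.sum())

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(5, 13))
            a = random_graph(rng, n, 0.35)
            nm = nodal_graph_metrics(a)
            assert np.allclose(nm.betweenness, oracle_betweenness(a),
                               atol=1e-9)
            _, _, _, _, _, nodal_eff = oracle_metrics(a)
            assert np.allclose(nm.efficiency, nodal_eff, atol=1e-12)


# ---------------------------------------------------------------- rewiring
class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        for _ in range(10):
            a = random_graph(rng, 20, 0.25)
            b = rewire_preserving_degree(a, rng=rng)
            assert np.array_equal(a.sum(1), b.sum(1))
            assert np.array_equal(b, b.T)
            assert not b.diagonal().any()

    def test_complete_graph_unchanged(self):
        a = ~np.eye(6, dtype=bool)
        with pytest.warns(UserWarning, match="budget"):
            b = rewire_preserving_degree(a, n_swaps=10, rng=0)
        assert np.array_equal(a, b)

    def test_deterministic_given_seed(self, rng):
        a = random_graph(rng, 20, 0.3)
        b1 = rewire_preserving_degree(a, rng=7)
        b2 = rewire_preserving_degree(a, rng=7)
        assert np.array_equal(b1, b2)

    def test_ring_lattice_clustering_decreases(self):
        n, k = 30, 4
        a = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                a[i, (i + d) % n] = a[(i + d) % n, i] = True
        cp0 = global_graph_metrics(a).Cp
        decreased = sum(
            global_graph_metrics(rewire_preserving_degree(a, rng=s)).Cp < cp0
            for s in range(100)
        )
        assert decreased >= 95


class TestSmallWorld:
    def test_complete_graph_exactly_one(self):
        a = ~np.eye(10, dtype=bool)
        with pytest.warns(UserWarning, match="budget"):
            gamma, lam, sigma = small_world_metrics(a, n_null=3, rng=0)
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_ring_lattice_high_gamma(self):
        n, k = 60, 4
        a = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                a[i, (i + d) % n] = a[(i + d) % n, i] = True
        gamma, _, _ = small_world_metrics(a, n_null=20, rng=3)
        assert gamma > 2.0

    def test_er_graph_is_its_own_null(self):
        rng = np.random.default_rng(4)
        a = random_graph(rng, 40, 0.25)
        gamma, lam, _ = small_world_metrics(a, n_null=20, rng=5)
        assert 0.85 < gamma < 1.15
        assert 0.9 < lam < 1.1


# ---------------------------------------------------------------- AUC
class TestAUC:
    def test_constant_curve(self):
        grid = np.arange(0.10, 0.501, 0.01)
        assert auc_over_sparsity(np.ones_like(grid), grid) == pytest.approx(0.4)

    def test_linear_ramp(self):
        grid = np.linspace(0.10, 0.50, 41)
        ramp = np.linspace(0, 1, 41)
        assert auc_over_sparsity(ramp, grid) == pytest.approx(0.2)

    def test_matches_trapezoid_sum_oracle(self, rng):
        grid = np.sort(rng.uniform(0.1, 0.5, 15))
        grid += np.arange(15) * 1e-6  # ensure strictly increasing
        vals = rng.normal(size=15)
        ref = sum(
            (vals[i] + vals[i + 1]) / 2 * (grid[i + 1] - grid[i])
            for i in range(14)
        )
        assert auc_over_sparsity(vals, grid) == pytest.approx(ref, abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            auc_over_sparsity([1, 2, 3], [0.1, 0.2])
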