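"""Permutation inference for group differences in network topology.

Each group contributes a *single* network per sparsity (connectivity is a
group-level construct), so parametric group comparisons are unavailable and
inference relies on permuting group membership: for every relabelling the
group networks are rebuilt from scratch and the metric recomputed.  The test
statistic collapses the sparsity sweep to one number per metric — the area
under the metric-vs-sparsity curve (AUC) — and the empirical two-tailed
p-value uses the +1 convention

    p = (1 + #{ |null| >= |observed| }) / (1 + n_perm),

so p is never exactly zero.  Nodal tests share one relabelling stream
across nodes, preserving cross-node dependence for the BH adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .connectivity import fdr_adjust
from .graphs import (
    DEFAULT_SPARSITIES,
    auc_over_sparsity,
    batched_bfs_distances,
    batched_global_metrics,
    betweenness_centrality,
    small_world_metrics,
    sparsity_sweep,
)

__all__ = [
    "GLOBAL_METRICS",
    "SMALL_WORLD_METRICS",
    "NODAL_METRICS",
    "PermutationResult",
    "metric_auc_curves",
    "group_metric_difference",
    "permutation_test",
    "permutation_test_multi",
    "nodal_permutation_tests",
]

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc")
SMALL_WORLD_METRICS = ("gamma", "lambda", "sigma")
NODAL_METRICS = ("degree", "betweenness", "efficiency")


@dataclass
class PermutationResult:
    metric: str
    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    rng_seed: int | None = None


def _corr(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def metric_auc_curves(
    x: np.ndarray,
    metrics,
    sparsities=DEFAULT_SPARSITIES,
    n_null: int = 100,
    rng: np.random.Generator | int | None = None,
    use_abs: bool = False,
) -> tuple[dict, dict]:
    """Metric curves over the sparsity sweep for one group's SUV matrix.

    ``metrics`` may mix global names (Cp, Lp, Eglob, Eloc, gamma, lambda,
    sigma) and nodal names (degree, betweenness, efficiency).  Returns
    ``(curves, aucs)``: per-metric arrays of shape (n_sparsity,) for global
    metrics and (n_sparsity, n_nodes) for nodal ones, plus their trapezoidal
    AUCs.  Small-world metrics need a rewired null ensemble of size
    ``n_null`` per sparsity (seeded by ``rng``).
    """
    x = np.asarray(x, dtype=float)
    metrics = tuple(metrics)
    sparsities = np.asarray(sparsities, dtype=float)
    want_global = any(m in GLOBAL_METRICS for m in metrics)
    want_sw = any(m in SMALL_WORLD_METRICS for m in metrics)
    want_nodal = [m for m in metrics if m in NODAL_METRICS]
    unknown = [
        m for m in metrics
        if m not in GLOBAL_METRICS + SMALL_WORLD_METRICS + NODAL_METRICS
    ]
    if unknown:
        raise ValueError(f"unknown metric(s): {unknown}")
    rng = np.random.default_rng(rng)

    r = _corr(x)
    n_nodes = r.shape[0]
    ns = sparsities.size
    curves: dict[str, np.ndarray] = {}
    for m in metrics:
        shape = (ns,) if m in GLOBAL_METRICS + SMALL_WORLD_METRICS else (ns, n_nodes)
        curves[m] = np.empty(shape)

    stack = np.empty((ns, n_nodes, n_nodes), dtype=bool)
    for k, (_, a) in enumerate(sparsity_sweep(r, sparsities, use_abs=use_abs)):
        stack[k] = a
        if want_sw:
            gamma, lam, sigma = small_world_metrics(a, n_null=n_null, rng=rng)
            for m, v in zip(("gamma", "lambda", "sigma"), (gamma, lam, sigma)):
                if m in curves:
                    curves[m][k] = v
        if "betweenness" in want_nodal:
            curves["betweenness"][k] = betweenness_centrality(a)

    if want_global:
        batch = batched_global_metrics(stack)
        for m in GLOBAL_METRICS:
            if m in curves:
                curves[m][:] = batch[m]
    if "degree" in want_nodal or "efficiency" in want_nodal:
        if "degree" in want_nodal:
            curves["degree"][:] = stack.sum(axis=2)
        if "efficiency" in want_nodal:
            dist = batched_bfs_distances(stack)
            with np.errstate(divide="ignore"):
                inv = 1.0 / dist
            inv[:, np.eye(n_nodes, dtype=bool)] = 0.0
            curves["efficiency"][:] = inv.sum(axis=2) / (n_nodes - 1)

    aucs = {
        m: (
            auc_over_sparsity(c, sparsities)
            if c.ndim == 1
            else np.trapezoid(c, sparsities, axis=0)
        )
        for m, c in curves.items()
    }
    return curves, aucs


def _split(labels) -> tuple[np.ndarray, np.ndarray, tuple]:
    g = np.asarray(labels)
    uniq = pd.unique(g)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two group labels, got {list(uniq)}")
    return np.flatnonzero(g == uniq[0]), np.flatnonzero(g == uniq[1]), tuple(uniq)


def group_metric_difference(
    suv_a: np.ndarray,
    suv_b: np.ndarray,
    metric: str,
    sparsities=DEFAULT_SPARSITIES,
    n_null: int = 100,
    rng: np.random.Generator | int | None = None,
):
    """Observed AUC difference, group A minus group B, for one metric."""
    _, auc_a = metric_auc_curves(suv_a, (metric,), sparsities, n_null, rng)
    _, auc_b = metric_auc_curves(suv_b, (metric,), sparsities, n_null, rng)
    return auc_a[metric] - auc_b[metric]


def permutation_test_multi(
    suv_all,
    labels,
    metrics=GLOBAL_METRICS,
    n_perm: int = 5000,
    rng_seed: int = 0,
    sparsities=DEFAULT_SPARSITIES,
    n_null: int = 100,
) -> dict[str, PermutationResult]:
    """Permutation tests for several metrics sharing one relabelling stream.

    The observed difference is first-label group minus second-label group.
    All requested metrics are evaluated on the same relabellings (one sweep
    per relabelled group), which both preserves their joint null dependence
    and does the work once.
    """
    x = np.asarray(
        suv_all.to_numpy() if isinstance(suv_all, pd.DataFrame) else suv_all,
        dtype=float,
    )
    metrics = (metrics,) if isinstance(metrics, str) else tuple(metrics)
    idx_a, idx_b, _ = _split(labels)
    n = x.shape[0]
    n_distinct = comb(n, idx_a.size)
    if n_perm > n_distinct:
        warnings.warn(
            f"n_perm={n_perm} exceeds the {n_distinct} distinct "
            "relabellings; sampling with replacement retained",
            stacklevel=2,
        )
    rng = np.random.default_rng(rng_seed)

    def stat(ia, ib):
        _, auc_a = metric_auc_curves(x[ia], metrics, sparsities, n_null, rng)
        _, auc_b = metric_auc_curves(x[ib], metrics, sparsities, n_null, rng)
        return {m: auc_a[m] - auc_b[m] for m in metrics}

    observed = stat(idx_a, idx_b)
    null = {m: np.empty(n_perm) for m in metrics}
    for k in range(n_perm):
        perm = rng.permutation(n)
        d = stat(perm[: idx_a.size], perm[idx_a.size:])
        for m in metrics:
            null[m][k] = d[m]
    out = {}
    for m in metrics:
        exceed = np.count_nonzero(np.abs(null[m]) >= abs(observed[m]))
        p = (1.0 + exceed) / (1.0 + n_perm)
        out[m] = PermutationResult(m, float(observed[m]), null[m], float(p),
                                   n_perm, rng_seed)
    return out


def permutation_test(
    suv_all,
    labels,
    metric: str = "Cp",
    n_perm: int = 5000,
    rng_seed: int = 0,
    sparsities=DEFAULT_SPARSITIES,
    n_null: int = 100,
) -> PermutationResult:
    """Permutation test for one global metric's AUC difference."""
    return permutation_test_multi(
        suv_all, labels, (metric,), n_perm, rng_seed, sparsities, n_null
    )[metric]


def nodal_permutation_tests(
    suv_all,
    labels,
    nodal_metric: str = "degree",
    n_perm: int = 5000,
    rng_seed: int = 0,
    sparsities=DEFAULT_SPARSITIES,
    region_names=None,
) -> pd.DataFrame:
    """Per-node permutation tests on a nodal metric's AUC, with BH q-values.

    All nodes share the same relabelling stream (the stream an equivalent
    :func:`permutation_test` would draw from the same seed), so node-wise
    null statistics retain their dependence.
    """
    if nodal_metric not in NODAL_METRICS:
        raise ValueError(f"nodal metric must be one of {NODAL_METRICS}")
    if isinstance(suv_all, pd.DataFrame):
        if region_names is None:
            region_names = list(suv_all.columns)
        x = suv_all.to_numpy(dtype=float)
    else:
        x = np.asarray(suv_all, dtype=float)
    if region_names is None:
        region_names = [f"ROI{i+1}" for i in range(x.shape[1])]
    idx_a, idx_b, _ = _split(labels)
    n = x.shape[0]
    rng = np.random.default_rng(rng_seed)

    def stat(ia, ib):
        _, auc_a = metric_auc_curves(x[ia], (nodal_metric,), sparsities)
        _, auc_b = metric_auc_curves(x[ib], (nodal_metric,), sparsities)
        return auc_a[nodal_metric] - auc_b[nodal_metric]

    observed = stat(idx_a, idx_b)
    null = np.empty((n_perm, observed.size))
    for k in range(n_perm):
        perm = rng.permutation(n)
        null[k] = stat(perm[: idx_a.size], perm[idx_a.size:])
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    out = pd.DataFrame(
        {
            "observed": observed,
            "p": p,
            "q": fdr_adjust(p),
            "n_perm": n_perm,
            "rng_seed": rng_seed,
        },
        index=region_names,
    )
    out.index.name = "region"
    out.attrs["metric"] = nodal_metric
    return out
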