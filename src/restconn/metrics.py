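"""Binary undirected graph metric panel.

Five metrics over a thresholded adjacency: node degree, nodal clustering
coefficient, nodal local efficiency, characteristic path length and
global efficiency.  Disconnected graphs are the norm at high absolute
thresholds, so the path length averages over reachable pairs only and
efficiency treats unreachable pairs as contributing zero (1/inf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import BinaryGraph
from .exceptions import UndefinedMetricError


@dataclass(frozen=True)
class NodalSummary:
    mean: float
    std: float
    n_used: int


@dataclass(frozen=True)
class GraphMetricsResult:
    """Metric panel for one binary graph.

    ``characteristic_path_length`` is ``None`` (with ``cpl_defined`` False)
    on an edgeless graph.  ``n_unreachable_pairs`` counts ordered node
    pairs excluded from the path-length average.
    """

    degree: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    characteristic_path_length: float | None
    global_efficiency: float
    cpl_defined: bool
    n_unreachable_pairs: int
    include_isolated: bool
    degree_summary: NodalSummary | None
    clustering_summary: NodalSummary | None
    local_efficiency_summary: NodalSummary | None


def node_degree(G: BinaryGraph) -> np.ndarray:
    """Edges incident to each node (row sums of the adjacency)."""
    return G.adjacency.sum(axis=1).astype(int)


def clustering_coefficient(G: BinaryGraph) -> np.ndarray:
    """C_i = 2 * triangles_i / (k_i (k_i - 1)); 0 where degree < 2.

    The fraction of a node's neighbour pairs that are themselves linked.
    """
    a = G.adjacency.astype(np.int64)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2 * triangles / np.where(denom > 0, denom, 1), 0.0)
    return c.astype(float)


def _distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    return shortest_path(adjacency.astype(float), method="D", unweighted=True)


def _efficiency_from_distances(d: np.ndarray) -> float:
    """Mean of 1/d over ordered distinct pairs, with 1/inf = 0."""
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def global_efficiency(G: BinaryGraph) -> float:
    """Average inverse shortest-path length over all ordered pairs."""
    return _efficiency_from_distances(_distance_matrix(G.adjacency))


def local_efficiency(G: BinaryGraph) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph.

    Zero where the node has fewer than two neighbours.
    """
    a = G.adjacency
    out = np.zeros(G.n)
    for i in range(G.n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = _efficiency_from_distances(_distance_matrix(sub))
    return out


def characteristic_path_length(G: BinaryGraph) -> tuple[float, int]:
    """Mean shortest-path distance over reachable ordered distinct pairs.

    Returns ``(cpl, n_unreachable_pairs)``.  Unreachable pairs are
    excluded from the average and counted.  Raises
    :class:`UndefinedMetricError` on an edgeless graph.
    """
    if connection_total(G) == 0:
        raise UndefinedMetricError("characteristic path length undefined: graph has no edges")
    d = _distance_matrix(G.adjacency)
    off = ~np.eye(G.n, dtype=bool)
    vals = d[off]
    reachable = np.isfinite(vals)
    return float(vals[reachable].mean()), int((~reachable).sum())


def connection_total(G: BinaryGraph) -> int:
    return int(G.adjacency.sum())


def nodal_summary(
    values: np.ndarray, degrees: np.ndarray, include_isolated: bool = False
) -> NodalSummary:
    """Mean and sample (n-1) std of a nodal metric.

    With ``include_isolated=False`` degree-0 nodes are dropped before
    averaging; the printed group tables of sparse networks are only
    consistent with that convention.  Raises
    :class:`UndefinedMetricError` if no nodes remain.
    """
    values = np.asarray(values, dtype=float)
    degrees = np.asarray(degrees)
    if values.shape != degrees.shape:
        raise ValueError("values and degrees must have equal length")
    used = values if include_isolated else values[degrees > 0]
    if used.size == 0:
        raise UndefinedMetricError("no nodes remain after excluding isolated nodes")
    std = float(used.std(ddof=1)) if used.size > 1 else 0.0
    return NodalSummary(float(used.mean()), std, int(used.size))


def compute_metrics(G: BinaryGraph, include_isolated: bool = False) -> GraphMetricsResult:
    """Full five-metric panel plus nodal summaries for one graph."""
    deg = node_degree(G)
    clust = clustering_coefficient(G)
    leff = local_efficiency(G)
    geff = global_efficiency(G)
    try:
        cpl, n_unreach = characteristic_path_length(G)
        cpl_defined = True
    except UndefinedMetricError:
        cpl, n_unreach, cpl_defined = None, G.n * (G.n - 1), False

    def _summ(vals):
        try:
            return nodal_summary(vals, deg, include_isolated)
        except UndefinedMetricError:
            return None

    return GraphMetricsResult(
        degree=deg,
        clustering=clust,
        local_efficiency=leff,
        characteristic_path_length=cpl,
        global_efficiency=geff,
        cpl_defined=cpl_defined,
        n_unreachable_pairs=n_unreach,
        include_isolated=include_isolated,
        degree_summary=_summ(deg.astype(float)),
        clustering_summary=_summ(clust),
        local_efficiency_summary=_summ(leff),
    )
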