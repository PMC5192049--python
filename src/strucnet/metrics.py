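"""Weighted graph-theory metrics for FA-weighted structural networks.

All metrics operate on symmetric nonnegative weight matrices and follow the
weighted conventions of the Brain Connectivity Toolbox:

* connection length is the inverse weight ``1/w`` (stronger = shorter);
* path length averages only over connected (finite-distance) node pairs;
* transitivity and clustering use the cube-root geometric-mean triangle
  intensity with weights normalised by the network maximum;
* assortativity correlates endpoint *strengths* over the edge list, each
  undirected edge contributing both orientations;
* betweenness is reported as raw unordered-pair counts, not normalised
  fractions.

Hubs are nodes whose group-averaged strength exceeds the across-node mean by
more than one sample standard deviation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .connectome import ConnectivityMatrix

__all__ = [
    "GlobalMetricsRecord",
    "NodalMetrics",
    "nodal_strength",
    "shortest_path_distances",
    "characteristic_path_length",
    "global_efficiency",
    "weighted_transitivity",
    "weighted_clustering",
    "assortativity",
    "betweenness_centrality",
    "detect_hubs",
    "global_metrics",
    "GLOBAL_METRIC_NAMES",
]

#: The six whole-brain measures reported per subject, in table order.
GLOBAL_METRIC_NAMES = (
    "strength",
    "transitivity",
    "global_efficiency",
    "assortativity",
    "path_length",
    "betweenness",
)

_TIE_TOL = 1e-12  # relative tolerance for equal-length shortest paths


class DegenerateGraphError(ValueError):
    """The requested metric is undefined on this graph (e.g. no finite path)."""


@dataclass
class GlobalMetricsRecord:
    """Whole-brain summary of one subject's network.

    ``assortativity`` is NaN with ``assortativity_defined=False`` when the
    endpoint-strength variance is zero (the correlation is undefined); it is
    never silently reported as 0.
    """

    mean_strength: float
    transitivity: float
    global_efficiency: float
    assortativity: float
    assortativity_defined: bool
    path_length: float
    mean_clustering: float
    mean_betweenness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "strength": self.mean_strength,
            "transitivity": self.transitivity,
            "global_efficiency": self.global_efficiency,
            "assortativity": self.assortativity,
            "path_length": self.path_length,
            "betweenness": self.mean_betweenness,
            "clustering": self.mean_clustering,
        }


@dataclass
class NodalMetrics:
    strength: np.ndarray
    betweenness: np.ndarray
    hub_flag: np.ndarray | None = None


def _weights(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ConnectivityMatrix):
        matrix.validate()
        return matrix.weights
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {w.shape}")
    if np.abs(w - w.T).max(initial=0.0) > 1e-9 or np.any(w < 0):
        raise ValueError("weight matrix must be symmetric and nonnegative")
    return w


def nodal_strength(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Strength of each node: the sum of its neighbouring link weights."""
    return _weights(matrix).sum(axis=1)


def shortest_path_distances(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length ``1/weight``.

    Dijkstra from every source; ``inf`` for disconnected pairs, 0 diagonal.
    """
    w = _weights(matrix)
    n = w.shape[0]
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    dist = _sp_dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(dist, 0.0)
    return dist


def characteristic_path_length(distances: np.ndarray) -> float:
    """Mean shortest-path distance over connected unordered pairs.

    Disconnected pairs are excluded; a graph with no finite off-diagonal
    distance raises :class:`DegenerateGraphError`.
    """
    iu = np.triu_indices(distances.shape[0], k=1)
    d = distances[iu]
    finite = np.isfinite(d)
    if not finite.any():
        raise DegenerateGraphError("no connected node pair: path length undefined")
    return float(d[finite].mean())


def global_efficiency(distances: np.ndarray) -> float:
    """Mean inverse shortest-path distance over unordered pairs (1/inf = 0)."""
    iu = np.triu_indices(distances.shape[0], k=1)
    d = distances[iu]
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv.mean()) if d.size else 0.0


def _triangle_intensity(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node geometric-mean triangle intensity t_i and binary degree k_i.

    Weights are normalised by the network maximum before the cube root, so
    the intensity of a triangle of maximal weights is 1.
    """
    w_max = w.max(initial=0.0)
    if w_max <= 0:
        n = w.shape[0]
        return np.zeros(n), np.zeros(n)
    cube = np.cbrt(w / w_max)
    t = np.einsum("ij,ih,jh->i", cube, cube, cube) / 2.0
    k = (w > 0).sum(axis=1).astype(float)
    return t, k


def weighted_transitivity(matrix: ConnectivityMatrix | np.ndarray) -> float:
    """Network-level ratio of weighted triangles to connected triplets.

    ``T = sum_i 2 t_i / sum_i k_i (k_i - 1)``; 0 when no node has degree >= 2.
    """
    w = _weights(matrix)
    t, k = _triangle_intensity(w)
    denom = (k * (k - 1)).sum()
    if denom <= 0:
        return 0.0
    return float(2.0 * t.sum() / denom)


def weighted_clustering(
    matrix: ConnectivityMatrix | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-node weighted clustering coefficient and its mean.

    ``c_i = 2 t_i / (k_i (k_i - 1))``, 0 for nodes of degree < 2.
    """
    w = _weights(matrix)
    t, k = _triangle_intensity(w)
    c = np.zeros_like(t)
    mask = k >= 2
    c[mask] = 2.0 * t[mask] / (k[mask] * (k[mask] - 1.0))
    return c, float(c.mean()) if c.size else 0.0


def assortativity(matrix: ConnectivityMatrix | np.ndarray) -> float:
    """Correlation of endpoint strengths across edges (weighted assortativity).

    Each undirected edge contributes both orientations.  Returns NaN (the
    explicit undefined marker) when the endpoint-strength variance is zero,
    e.g. on regular graphs; raises on an edgeless matrix.
    """
    w = _weights(matrix)
    s = w.sum(axis=1)
    ii, jj = np.nonzero(np.triu(w, k=1))
    if ii.size == 0:
        raise DegenerateGraphError("assortativity undefined on an edgeless graph")
    x = np.concatenate([s[ii], s[jj]])
    y = np.concatenate([s[jj], s[ii]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def betweenness_centrality(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Weighted betweenness: shortest-path pair counts through each node.

    For node ``v``, the sum over unordered pairs ``(s, t)`` (both distinct
    from ``v``) of the fraction of shortest weighted paths between ``s`` and
    ``t`` that pass through ``v``.  Connection lengths are ``1/w``; path
    counting is multiplicity-aware (Brandes single-source accumulation).
    """
    w = _weights(matrix)
    n = w.shape[0]
    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                length = 1.0 / w[i, j]
                neighbors[i].append((j, length))
                neighbors[j].append((i, length))
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s] = 0.0
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        settled_order: list[int] = []
        done = np.zeros(n, dtype=bool)
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            settled_order.append(v)
            for u, length in neighbors[v]:
                if done[u]:
                    continue
                alt = d + length
                tol = _TIE_TOL * max(1.0, abs(alt))
                if alt < dist[u] - tol:
                    dist[u] = alt
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (alt, u))
                elif abs(alt - dist[u]) <= tol:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        delta = np.zeros(n)
        for v in reversed(settled_order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    return bc / 2.0  # each unordered pair accumulated from both endpoints


def detect_hubs(
    group_matrices: list[ConnectivityMatrix] | list[np.ndarray],
) -> tuple[np.ndarray, float, np.ndarray]:
    """Hub classification from a group of subjects' networks.

    Each node's strength is averaged across subjects; a node is a hub iff its
    group-mean strength strictly exceeds ``mean + 1 SD`` of the across-node
    distribution (sample SD, ``n - 1`` denominator).  Ties at the threshold
    are not hubs.

    Returns ``(hub_flags, threshold, group_mean_strength)``.
    """
    if not group_matrices:
        raise ValueError("at least one matrix required")
    labels = None
    strengths = []
    for m in group_matrices:
        if isinstance(m, ConnectivityMatrix):
            if labels is None:
                labels = m.node_labels
            elif m.node_labels != labels:
                raise ValueError("matrices have inconsistent node labels")
        strengths.append(nodal_strength(m))
    mean_strength = np.mean(strengths, axis=0)
    threshold = float(mean_strength.mean() + mean_strength.std(ddof=1))
    return mean_strength > threshold, threshold, mean_strength


def global_metrics(matrix: ConnectivityMatrix | np.ndarray) -> GlobalMetricsRecord:
    """All whole-brain measures of one network in a single record."""
    w = _weights(matrix)
    s = w.sum(axis=1)
    dist = shortest_path_distances(w)
    try:
        a = assortativity(w)
    except DegenerateGraphError:
        a = float("nan")
    _, mean_c = weighted_clustering(w)
    return GlobalMetricsRecord(
        mean_strength=float(s.mean()),
        transitivity=weighted_transitivity(w),
        global_efficiency=global_efficiency(dist),
        assortativity=a,
        assortativity_defined=bool(np.isfinite(a)),
        path_length=characteristic_path_length(dist),
        mean_clustering=mean_c,
        mean_betweenness=float(betweenness_centrality(w).mean()),
    )
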