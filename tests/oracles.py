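"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the algorithms used in the package: distances via
Floyd-Warshall instead of Dijkstra, triangle sums via explicit triple loops
instead of einsum, betweenness via exhaustive simple-path enumeration
instead of Brandes accumulation, and step-up FDR via the direct
min-over-tail definition instead of statsmodels.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances on lengths 1/w, by triple relaxation."""
    n = w.shape[0]
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_strength(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(w[i, j] for j in range(n)) for i in range(n)])


def brute_triangle_terms(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(t_i, k_i) with cube-root geometric-mean weights, max-normalised."""
    n = w.shape[0]
    w_max = w.max() if w.max() > 0 else 1.0
    t = np.zeros(n)
    k = np.zeros(n)
    for i in range(n):
        k[i] = sum(1 for j in range(n) if w[i, j] > 0)
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (
                        (w[i, j] / w_max) * (w[i, h] / w_max) * (w[j, h] / w_max)
                    ) ** (1.0 / 3.0)
        t[i] = acc / 2.0
    return t, k


def brute_transitivity(w: np.ndarray) -> float:
    t, k = brute_triangle_terms(w)
    denom = sum(ki * (ki - 1) for ki in k)
    return 0.0 if denom == 0 else 2.0 * t.sum() / denom


def brute_clustering_mean(w: np.ndarray) -> float:
    t, k = brute_triangle_terms(w)
    c = [2.0 * ti / (ki * (ki - 1)) if ki >= 2 else 0.0 for ti, ki in zip(t, k)]
    return float(np.mean(c))


def brute_assortativity(w: np.ndarray) -> float:
    """Direct correlation formula over the directed edge list of strengths."""
    n = w.shape[0]
    s = brute_strength(w)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                xs.append(s[i])
                ys.append(s[j])
    x = np.array(xs)
    y = np.array(ys)
    vx = ((x - x.mean()) ** 2).sum()
    vy = ((y - y.mean()) ** 2).sum()
    if vx == 0 or vy == 0:
        return math.nan
    return float(((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(vx * vy))


def brute_betweenness(w: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Exhaustive enumeration of all simple paths per pair.

    For every unordered pair, enumerate every simple path, find the minimal
    length, count the multiplicity, and credit interior nodes with the
    fraction of minimal paths passing through them.
    """
    n = w.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths: list[tuple[float, tuple[int, ...]]] = []

        def extend(node: int, visited: tuple[int, ...], length: float) -> None:
            for nxt in range(n):
                if w[node, nxt] > 0 and nxt not in visited:
                    new_len = length + 1.0 / w[node, nxt]
                    if nxt == t:
                        paths.append((new_len, visited + (nxt,)))
                    else:
                        extend(nxt, visited + (nxt,), new_len)

        extend(s, (s,), 0.0)
        if not paths:
            continue
        best = min(length for length, _ in paths)
        minimal = [p for length, p in paths if length <= best * (1 + tol)]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in minimal if v in p)
            bc[v] += through / len(minimal)
    return bc


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Adjusted p-values by the literal min-over-tail definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_idx, i in enumerate(order):
        tail = [
            p[order[j]] * m / (j + 1) for j in range(rank_idx, m)
        ]
        adj[i] = min(1.0, min(tail))
    return adj


def random_weighted_graph(
    rng: np.random.Generator, n_max: int = 6, density: float = 0.6
) -> np.ndarray:
    """Random symmetric weight matrix with weights in (0, 1]."""
    n = int(rng.integers(3, n_max + 1))
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < density:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w
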