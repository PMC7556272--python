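"""Brute-force reference implementations, independent of the package.

Deliberately naive: exhaustive triple/double sums, Floyd-Warshall,
shortest-path enumeration and hypergeometric enumeration.  Used to pin
the production implementations on small random instances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.stats


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    d = lengths.copy().astype(float)
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_onnela(adj: np.ndarray) -> float:
    n = adj.shape[0]
    wmax = adj.max()
    if wmax <= 0:
        raise ValueError("empty graph")
    w = adj / wmax
    cs = []
    for i in range(n):
        k = int((adj[i] > 0).sum())
        if k < 2:
            cs.append(0.0)
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        cs.append(total / (k * (k - 1)))
    return float(np.mean(cs))


def path_length_and_efficiency(adj: np.ndarray) -> tuple[float, float, float]:
    """(L over reachable pairs, GE, unreachable fraction) via Floyd-Warshall."""
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), np.inf)
    d = floyd_warshall(lengths)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    l = float(d[finite].mean())
    inv = np.where(finite, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    ge = float(inv[off].mean())
    return l, ge, 1.0 - finite.sum() / off.sum()


def betweenness_enumeration(adj: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unordered-pair betweenness by exhaustive simple-path enumeration.

    For every node pair, every simple path is enumerated, the shortest
    length found and the fraction of shortest paths crossing each
    intermediate vertex accumulated.  Exponential; only for tiny graphs.
    """
    n = adj.shape[0]
    bc = np.zeros(n)
    nodes = range(n)
    neighbors = [np.flatnonzero(adj[i] > 0) for i in nodes]

    def all_paths(s, t):
        stack = [(s, [s], 0.0)]
        while stack:
            v, path, dist = stack.pop()
            if v == t:
                yield path, dist
                continue
            for u in neighbors[v]:
                if u not in path:
                    stack.append((u, path + [int(u)], dist + 1.0 / adj[v, u]))

    for s, t in itertools.combinations(nodes, 2):
        paths = list(all_paths(s, t))
        if not paths:
            continue
        best = min(d for _, d in paths)
        shortest = [p for p, d in paths if d <= best * (1 + tol)]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def betweenness_path_counting(adj: np.ndarray) -> np.ndarray:
    """Independent betweenness oracle by shortest-path counting.

    Distances come from Floyd-Warshall; the number of shortest paths
    sigma[s, t] is a DP over nodes in order of distance from s; then
    bc(v) = sum over unordered pairs {s, t} not containing v of
    sigma[s, v] * sigma[v, t] / sigma[s, t] whenever v lies on a
    shortest s-t path.  No Brandes accumulation is used.
    """
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), np.inf)
    d = floyd_warshall(lengths)

    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for v in sorted(range(n), key=lambda x: d[s, x]):
            if v == s or not np.isfinite(d[s, v]):
                continue
            for u in range(n):
                if adj[u, v] > 0 and math.isclose(
                    d[s, u] + lengths[u, v], d[s, v], rel_tol=1e-12
                ):
                    sigma[s, v] += sigma[s, u]

    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t) or not np.isfinite(d[s, v]) or not np.isfinite(d[v, t]):
                    continue
                if math.isclose(d[s, v] + d[v, t], d[s, t], rel_tol=1e-12):
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def modularity_double_sum(adj: np.ndarray, labels: np.ndarray) -> float:
    n = adj.shape[0]
    two_m = adj.sum()
    s = adj.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - s[i] * s[j] / two_m
    return q / two_m


def fisher_exact_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities of all
    tables with the same margins that are no more probable than observed."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    row1, col1, total = a + b, a + c, a + b + c + d
    rv = scipy.stats.hypergeom(total, col1, row1)
    p_obs = rv.pmf(a)
    p = 0.0
    for x in range(max(0, row1 + col1 - total), min(row1, col1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(1.0, float(p))
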