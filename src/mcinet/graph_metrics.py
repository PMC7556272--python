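"""Scale-I global metrics on weighted networks.

Clustering coefficient C (Onnela weighted form, weights normalized by the
network maximum), characteristic path length L and global efficiency GE on
shortest paths with edge length 1/w, and small-worldness SW measured
against degree-preserving rewired nulls (weights travel with the swapped
edges).  L averages over reachable pairs only; the unreachable fraction is
reported alongside, since isolated ROIs exist at the sparsest thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ThresholdedNetwork


@dataclass
class GlobalMetrics:
    C: float
    L: float
    GE: float
    SW: float | None
    n_random: int
    unreachable_pair_fraction: float


def edge_lengths(net: ThresholdedNetwork) -> np.ndarray:
    """Length 1/w for retained edges, +inf otherwise (diagonal 0)."""
    adj = net.adjacency
    retained = adj > 0
    if np.any(adj[retained] <= 0):
        raise ValueError("retained edge with non-positive weight")
    lengths = np.full_like(adj, np.inf)
    lengths[retained] = 1.0 / adj[retained]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def clustering_coefficient(net: ThresholdedNetwork) -> float:
    """Mean Onnela weighted clustering over all N nodes.

    C_i = (1 / k_i(k_i - 1)) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) with
    w' = w / max(w); nodes of degree < 2 contribute 0.
    """
    adj = net.adjacency
    wmax = adj.max()
    if wmax <= 0:
        raise ValueError("empty network")
    w3 = np.cbrt(adj / wmax)
    k = (adj > 0).sum(axis=1)
    numer = np.diag(w3 @ w3 @ w3)
    denom = k * (k - 1)
    c = np.divide(numer, denom, out=np.zeros_like(numer, dtype=float), where=denom > 0)
    return float(c.mean())


def _distances(net: ThresholdedNetwork) -> np.ndarray:
    return shortest_path(edge_lengths(net), method="D", directed=False)


def characteristic_path_length(net: ThresholdedNetwork) -> tuple[float, float]:
    """(L over reachable ordered pairs i != j, unreachable pair fraction)."""
    d = _distances(net)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no reachable node pairs")
    unreachable = float(1.0 - finite.sum() / off.sum())
    return float(d[finite].mean()), unreachable


def global_efficiency(net: ThresholdedNetwork) -> float:
    """Mean inverse shortest-path distance, 1/inf = 0 for unreachable pairs."""
    d = _distances(net)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def rewire_preserving_degree(
    net: ThresholdedNetwork, seed: int, swaps_per_edge: int = 10
) -> ThresholdedNetwork:
    """Maslov-Sneppen double-edge swaps; weights travel with the edges.

    Attempts swaps_per_edge * K swaps (a,b)+(c,d) -> (a,d)+(c,b), each
    rejected if it would create a self-loop or multi-edge.  Degree
    sequence and the multiset of edge weights are preserved exactly.
    """
    ii, jj, ww = net.edge_list()
    k = ii.size
    if k < 2:
        return ThresholdedNetwork(net.adjacency.copy(), net.sparsity, net.retained_edges)
    u = ii.copy()
    v = jj.copy()
    w = ww.copy()
    present = {(int(a), int(b)) for a, b in zip(u, v)}
    rng = np.random.default_rng(seed)
    n_attempts = swaps_per_edge * k
    e1s = rng.integers(0, k, size=n_attempts)
    e2s = rng.integers(0, k, size=n_attempts)
    flips = rng.random(n_attempts) < 0.5
    for e1, e2, flip in zip(e1s, e2s, flips):
        if e1 == e2:
            continue
        a, b = int(u[e1]), int(v[e1])
        c, d = int(u[e2]), int(v[e2])
        if flip:
            c, d = d, c
        # proposed new edges: (a, d) and (c, b)
        if a == d or c == b:
            continue
        p, q = (a, d) if a < d else (d, a)
        r, s = (c, b) if c < b else (b, c)
        if (p, q) in present or (r, s) in present or (p, q) == (r, s):
            continue
        present.discard((a, b))
        present.discard((min(c, d), max(c, d)))
        present.add((p, q))
        present.add((r, s))
        u[e1], v[e1] = p, q
        u[e2], v[e2] = r, s
    adj = np.zeros_like(net.adjacency)
    adj[u, v] = w
    adj[v, u] = w
    return ThresholdedNetwork(adjacency=adj, sparsity=net.sparsity, retained_edges=net.retained_edges)


def small_worldness(
    net: ThresholdedNetwork,
    n_random: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> tuple[float, int]:
    """SW = (C / <C_rand>) / (L / <L_rand>) over rewired nulls.

    Null k uses seed + k.  Nulls with undefined L are dropped; the count
    of nulls actually used is returned alongside.
    """
    c_obs = clustering_coefficient(net)
    l_obs, _ = characteristic_path_length(net)
    c_rand: list[float] = []
    l_rand: list[float] = []
    for k in range(1, n_random + 1):
        null = rewire_preserving_degree(net, seed=seed + k, swaps_per_edge=swaps_per_edge)
        try:
            l_null, _ = characteristic_path_length(null)
        except ValueError:
            continue
        c_rand.append(clustering_coefficient(null))
        l_rand.append(l_null)
    if not c_rand:
        raise ValueError("all null networks had undefined path length")
    if len(c_rand) < n_random:
        warnings.warn(f"{n_random - len(c_rand)} null network(s) dropped", stacklevel=2)
    sw = (c_obs / np.mean(c_rand)) / (l_obs / np.mean(l_rand))
    return float(sw), len(c_rand)


def global_metrics(
    net: ThresholdedNetwork,
    n_random: int = 1000,
    seed: int = 0,
    compute_sw: bool = True,
) -> GlobalMetrics:
    """All scale-I metrics for one network."""
    c = clustering_coefficient(net)
    l, unreachable = characteristic_path_length(net)
    ge = global_efficiency(net)
    if compute_sw:
        sw, n_used = small_worldness(net, n_random=n_random, seed=seed)
    else:
        sw, n_used = None, 0
    return GlobalMetrics(C=c, L=l, GE=ge, SW=sw, n_random=n_used, unreachable_pair_fraction=unreachable)
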