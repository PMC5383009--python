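"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (hand-rolled
BFS, explicit shortest-path enumeration, exact rational arithmetic, a
minimal dense MCL) and shares no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def adjacency(graph) -> dict:
    adj: dict = {v: set() for v in graph.nodes}
    for u, v in graph.edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def cpl_oracle(graph) -> float:
    """Mean distance over connected unordered pairs; NaN when none exist."""
    adj = adjacency(graph)
    nodes = sorted(adj)
    total, pairs = 0, 0
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1 :]:
            if t in dist:
                total += dist[t]
                pairs += 1
    return total / pairs if pairs else float("nan")


def clustering_oracle(graph) -> tuple[dict, float]:
    """Local clustering by explicit neighbour-pair counting; mean over all nodes."""
    adj = adjacency(graph)
    local = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            local[v] = 0.0
            continue
        nbrs = sorted(nbrs)
        links = sum(
            1
            for i, a in enumerate(nbrs)
            for b in nbrs[i + 1 :]
            if b in adj[a]
        )
        local[v] = 2 * links / (k * (k - 1))
    mean = sum(local.values()) / len(local) if local else 0.0
    return local, mean


def _all_shortest_paths(adj: dict, s, t, dist_from_t: dict):
    """Enumerate every shortest s-t path by descending the distance field."""
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for w in adj[u]:
            if dist_from_t.get(w, -1) == dist_from_t[u] - 1:
                path.append(w)
                extend(path)
                path.pop()

    if t in dist_from_t and s in dist_from_t:
        extend([s])
    return paths


def betweenness_oracle(graph) -> dict:
    """Raw betweenness by complete shortest-path enumeration (small graphs only)."""
    adj = adjacency(graph)
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            dist_from_t = bfs_distances(adj, t)
            if s not in dist_from_t:
                continue
            paths = _all_shortest_paths(adj, s, t, dist_from_t)
            share = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += share
    return bc


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P[X >= k] by direct summation with exact binomial coefficients."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Hand-applied BH step-up: sort, scale by m/i, monotonise downward, cap."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    scaled = [pvalues[idx] * m / (rank + 1) for rank, idx in enumerate(indexed)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(indexed):
        out[idx] = min(scaled[rank], 1.0)
    return out


def reference_mcl(graph, inflation: float = 1.8, prune: float = 1e-5) -> frozenset:
    """Minimal dense MCL with the same conventions, independently coded.

    Returns the partition as a frozenset of frozensets.
    """
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v in graph.edges:
        if u != v:
            m[idx[u], idx[v]] = m[idx[v], idx[u]] = 1.0
    m += np.eye(n)
    m /= m.sum(0)
    for _ in range(100):
        prev = m.copy()
        m = m @ m
        m = m**inflation
        m /= m.sum(0)
        m[m < prune] = 0.0
        m /= m.sum(0)
        if np.abs(m - prev).max() < 1e-8:
            break
    att = [i for i in range(n) if m[i, i] > 0]
    sysid = {i: i for i in att}
    changed = True
    while changed:
        changed = False
        for i in att:
            for j in att:
                if (m[i, j] > 0 or m[j, i] > 0) and sysid[i] != sysid[j]:
                    low = min(sysid[i], sysid[j])
                    sysid[i] = sysid[j] = low
                    changed = True
    systems: dict = {}
    for i in att:
        systems.setdefault(sysid[i], []).append(i)
    clusters: dict = {}
    for col in range(n):
        best, best_mass = None, -1.0
        for root in sorted(systems):
            mass = sum(m[i, col] for i in systems[root])
            if mass > best_mass + 1e-15:
                best, best_mass = root, mass
        key = best if best_mass > 0 else -col - 1
        clusters.setdefault(key, set()).add(nodes[col])
    return frozenset(frozenset(c) for c in clusters.values())
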