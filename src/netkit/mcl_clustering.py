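"""Markov Clustering (MCL), implemented from scratch on dense matrices.

MCL simulates flow on the graph: a column-stochastic transition matrix is
alternately *expanded* (matrix power e, letting flow spread along paths) and
*inflated* (entrywise power r followed by column renormalisation, which
strengthens strong currents and starves weak ones).  The process converges
to a sparse idempotent-like limit whose attractor structure defines the
clusters.  The inflation parameter r controls granularity: r = 1.8 is the
customary setting for protein-interaction networks — larger values fragment
the graph into many small clusters.

Networks at interactome scale (a few thousand nodes) iterate comfortably as
dense numpy arrays; entries below the prune threshold are zeroed and columns
renormalised each cycle, which is what keeps the limit sparse.

Cluster extraction: attractors are nodes that retain flow onto themselves
(positive diagonal).  Attractors whose rows overlap form one attractor
system; every node is assigned to the system receiving the largest share of
its outgoing flow, with ties going to the system with the lexicographically
smallest representative.  The result is always a partition of the node set,
and flow can never cross connected components, so MCL never merges
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParametersError
from .graph_core import Network

logger = logging.getLogger(__name__)


@dataclass
class MCLParams:
    """Tunable parameters of the MCL iteration."""

    inflation: float = 1.8
    expansion: int = 2
    self_loop_weight: float = 1.0
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-8
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise InvalidParametersError("inflation must be > 1")
        if self.expansion < 2:
            raise InvalidParametersError("expansion must be >= 2")
        if self.prune_threshold < 0:
            raise InvalidParametersError("prune_threshold must be >= 0")
        if self.convergence_tol <= 0 or self.max_iterations < 1:
            raise InvalidParametersError("tolerances must be positive")


@dataclass
class ClusterSet:
    """Disjoint node groups covering the network, plus run metadata."""

    clusters: list[set[str]]
    params: MCLParams
    iterations_used: int
    converged: bool
    node_order: list[str] = field(default_factory=list)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def labels(self) -> dict[str, int]:
        """node -> cluster index (clusters ordered by size desc)."""
        out: dict[str, int] = {}
        for i, cluster in enumerate(self.clusters):
            for v in cluster:
                out[v] = i
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, v) for i, cluster in enumerate(self.clusters) for v in sorted(cluster)
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "accession"])


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def _inflate(m: np.ndarray, r: float) -> np.ndarray:
    return _normalize_columns(np.power(m, r))


def _prune(m: np.ndarray, threshold: float) -> np.ndarray:
    if threshold > 0:
        m = np.where(m < threshold, 0.0, m)
    return _normalize_columns(m)


def mcl_cluster(network: Network, params: MCLParams | None = None) -> ClusterSet:
    """Run MCL on an unweighted network and return the node partition.

    Non-convergence within ``max_iterations`` is not an error: the current
    partition is returned with ``converged=False`` and a log warning.
    """
    params = params or MCLParams()
    nodes = sorted(network.nodes)
    if not nodes:
        raise EmptyInputError("cannot cluster an empty network")
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in network.edges:
        if u == v:
            continue
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    np.fill_diagonal(a, params.self_loop_weight)
    m = _normalize_columns(a)

    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = _inflate(m, params.inflation)
        m = _prune(m, params.prune_threshold)
        if np.max(np.abs(m - prev)) < params.convergence_tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", params.max_iterations)

    clusters = _extract_clusters(m, nodes)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterSet(
        clusters=clusters,
        params=params,
        iterations_used=iterations,
        converged=converged,
        node_order=nodes,
    )


def _extract_clusters(m: np.ndarray, nodes: list[str]) -> list[set[str]]:
    """Partition from the limit matrix (columns = source nodes)."""
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    if not attractors:
        # fully degenerate limit; fall back to nonzero-structure components
        attractors = [int(np.argmax(m[:, j])) for j in range(n)]
        attractors = sorted(set(attractors))

    # group attractors into systems: attractors sharing any supported node
    parent = {i: i for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    # two attractors belong to one system iff flow links them directly;
    # sharing a plain (non-attractor) node is overlap, resolved by mass below
    for i in attractors:
        for j in attractors:
            if j > i and (m[i, j] > 0 or m[j, i] > 0):
                union(i, j)
    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)

    # assign every node to the system with the largest incoming flow share
    assignment: dict[int, int] = {}
    roots = sorted(systems)  # root == smallest representative index
    for j in range(n):
        best_root, best_mass = None, -1.0
        for root in roots:
            mass = float(sum(m[i, j] for i in systems[root]))
            if mass > best_mass + 1e-15:
                best_root, best_mass = root, mass
        if best_mass <= 0:
            assignment[j] = -j - 1  # isolated: singleton cluster
        else:
            assignment[j] = best_root
    clusters: dict[int, set[str]] = {}
    for j, root in assignment.items():
        clusters.setdefault(root, set()).add(nodes[j])
    return list(clusters.values())


def filter_clusters(
    cluster_set: ClusterSet, min_size: int = 3
) -> tuple[list[set[str]], list[set[str]]]:
    """Split clusters into kept (size >= min_size, descending size) and dropped."""
    kept = [c for c in cluster_set.clusters if len(c) >= min_size]
    dropped = [c for c in cluster_set.clusters if len(c) < min_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    dropped.sort(key=lambda c: (-len(c), min(c)))
    return kept, dropped


def inflation_sweep(
    network: Network,
    inflations: list[float] | None = None,
    *,
    base_params: MCLParams | None = None,
) -> pd.DataFrame:
    """Cluster once per inflation value; summarise granularity per value."""
    if inflations is None:
        inflations = [round(1.8 + 0.2 * i, 1) for i in range(7)]  # 1.8 .. 3.0
    if not inflations:
        raise EmptyInputError("inflation list is empty")
    base = base_params or MCLParams()
    rows = []
    for r in inflations:
        params = MCLParams(
            inflation=r,
            expansion=base.expansion,
            self_loop_weight=base.self_loop_weight,
            prune_threshold=base.prune_threshold,
            convergence_tol=base.convergence_tol,
            max_iterations=base.max_iterations,
        )
        cs = mcl_cluster(network, params)
        sizes = cs.sizes()
        rows.append(
            {
                "inflation": r,
                "n_clusters": len(sizes),
                "n_clusters_ge3": sum(1 for s in sizes if s >= 3),
                "max_cluster_size": max(sizes),
            }
        )
    return pd.DataFrame(rows)
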