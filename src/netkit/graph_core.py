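"""Undirected simple-graph model and the topology primitives downstream stages consume.

Networks are plain :class:`networkx.Graph` objects whose nodes are protein
accession strings.  Node metadata lives in the standard attribute dictionary:

``label``
    display abbreviation (e.g. ``"Aβ"``),
``category``
    one of :data:`NODE_CATEGORIES` (``"other"`` for plain interactors),
``roles``
    subset of ``{"hub", "bottleneck"}`` assigned by centrality calling.

All statistics treat the graph as unweighted and undirected.  Disconnected
graphs are first-class citizens: the characteristic path length averages over
connected pairs only (the convention of Cytoscape's NetworkAnalyzer), and the
no-connected-pair case is signalled with a NaN sentinel rather than an
exception so that removal trajectories can record it in-place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.sparse import csgraph

from .errors import DegenerateGraphError, EmptyInputError, MissingNodeError

#: Node categories used throughout: red / yellow / yellow / green in the map.
NODE_CATEGORIES = ("in_vivo_amyloid", "in_vitro_amyloid", "amyloid_related", "other")

#: Sentinel for "no connected pair exists" (characteristic path length).
NO_PATHS = float("nan")

#: Sentinel for an unreachable node pair (shortest path length).
UNREACHABLE = float("inf")

Network = nx.Graph


def new_network(edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()) -> Network:
    """Build a simple undirected network, silently dropping self-pairs.

    Nodes may be supplied separately to allow isolated nodes.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b) for a, b in edges if a != b)
    for v in g.nodes:
        g.nodes[v].setdefault("category", "other")
        g.nodes[v].setdefault("roles", set())
    return g


def validate_simple(network: Network) -> None:
    """Assert the structural invariants of a protein network."""
    if any(u == v for u, v in network.edges):
        raise ValueError("network contains a self-loop")
    if network.is_multigraph() or network.is_directed():
        raise ValueError("network must be a simple undirected graph")


@dataclass
class TopologySummary:
    """Headline statistics of one network.

    ``degree_histogram`` maps degree k to the number of nodes with that degree
    and sums to n; ``betweenness`` holds raw (unnormalised) values.
    """

    n: int
    m: int
    density: float
    cc: float
    cpl: float
    degree_histogram: dict[int, int]
    betweenness: dict[str, float]
    n_components: int
    giant_component_size: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "density": self.density,
            "cc": self.cc,
            "cpl": self.cpl,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
            "n_components": self.n_components,
            "giant_component_size": self.giant_component_size,
            **self.extras,
        }


def density(network: Network) -> float:
    """Edge density 2m / (n(n-1)).

    Raises
    ------
    DegenerateGraphError
        for graphs with fewer than two nodes, where density is undefined.
    """
    n = network.number_of_nodes()
    if n < 2:
        raise DegenerateGraphError(f"density undefined for n={n} < 2")
    return nx.density(network)


def characteristic_path_length(network: Network) -> float:
    """Mean shortest-path hop count over connected unordered node pairs.

    Unreachable pairs are excluded from the average.  Returns the NaN
    sentinel :data:`NO_PATHS` when no connected pair exists (edgeless or
    empty graph).
    """
    if network.number_of_edges() == 0:
        return NO_PATHS
    adj = nx.to_scipy_sparse_array(network, format="csr", weight=None)
    dist = csgraph.shortest_path(adj, method="D", unweighted=True, directed=False)
    finite = np.isfinite(dist) & (dist > 0)
    pairs = int(finite.sum())  # counts each unordered pair twice
    if pairs == 0:
        return NO_PATHS
    return float(dist[finite].sum() / pairs)


def clustering_coefficients(
    network: Network, *, exclude_low_degree: bool = False
) -> tuple[dict[str, float], float]:
    """Local clustering per node and the network mean.

    Local clustering of a node with degree k >= 2 is the fraction of its
    neighbour pairs that are themselves adjacent; nodes with k < 2 score 0.
    By default the mean runs over all nodes; ``exclude_low_degree=True``
    averages over degree >= 2 nodes only (both conventions occur in network
    analyzers and published values rarely state which was used).
    """
    local = nx.clustering(network)
    local = {v: float(c) for v, c in local.items()}
    if exclude_low_degree:
        vals = [c for v, c in local.items() if network.degree(v) >= 2]
    else:
        vals = list(local.values())
    mean = sum(vals) / len(vals) if vals else 0.0
    return local, mean


def betweenness(network: Network) -> tuple[dict[str, float], dict[str, float]]:
    """Shortest-path betweenness centrality, raw and normalised.

    Raw values count, for each node v, the share-weighted number of shortest
    paths between other node pairs passing through v (equal-length paths
    split evenly).  Normalised values divide by (n-1)(n-2)/2.
    Normalisation never changes the rank order.
    """
    raw = nx.betweenness_centrality(network, normalized=False)
    n = network.number_of_nodes()
    denom = (n - 1) * (n - 2) / 2
    norm = {v: (b / denom if denom > 0 else 0.0) for v, b in raw.items()}
    return ({v: float(b) for v, b in raw.items()}, norm)


def shortest_path_length(network: Network, source: str, target: str) -> float:
    """Minimum hop count between two nodes; :data:`UNREACHABLE` if disconnected."""
    for v in (source, target):
        if v not in network:
            raise MissingNodeError(v)
    try:
        return float(nx.shortest_path_length(network, source, target))
    except nx.NetworkXNoPath:
        return UNREACHABLE


def components(network: Network) -> list[set[str]]:
    """Connected components, largest first; ties broken by smallest member."""
    comps = [set(c) for c in nx.connected_components(network)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def giant_component(network: Network) -> Network:
    """The largest connected component as a subgraph copy (ties: smallest member)."""
    comps = components(network)
    if not comps:
        return new_network()
    return network.subgraph(comps[0]).copy()


def subnetwork(network: Network, centers: Iterable[str], radius: int = 1) -> Network:
    """Induced subgraph on ``centers`` plus every node within ``radius`` hops."""
    centers = list(centers)
    if not centers:
        raise EmptyInputError("subnetwork requires at least one center node")
    for c in centers:
        if c not in network:
            raise MissingNodeError(c)
    keep: set[str] = set()
    for c in centers:
        keep |= set(nx.single_source_shortest_path_length(network, c, cutoff=radius))
    return network.subgraph(keep).copy()


def degree_histogram(network: Network) -> dict[int, int]:
    """Map degree k -> number of nodes with that degree (sums to n)."""
    hist: dict[int, int] = {}
    for _, k in network.degree():
        hist[k] = hist.get(k, 0) + 1
    return hist


def summarize(network: Network, *, exclude_low_degree: bool = False) -> TopologySummary:
    """Compute the full simple-topology summary of a network."""
    n = network.number_of_nodes()
    m = network.number_of_edges()
    _, cc = clustering_coefficients(network, exclude_low_degree=exclude_low_degree)
    raw_bc, _ = betweenness(network)
    comps = components(network)
    return TopologySummary(
        n=n,
        m=m,
        density=density(network) if n >= 2 else 0.0,
        cc=cc,
        cpl=characteristic_path_length(network),
        degree_histogram=degree_histogram(network),
        betweenness=raw_bc,
        n_components=len(comps),
        giant_component_size=len(comps[0]) if comps else 0,
    )


def relabel_categories(network: Network, categories: Mapping[str, str]) -> None:
    """Attach category labels in place; unlisted nodes become ``"other"``."""
    for v in network.nodes:
        network.nodes[v]["category"] = categories.get(v, "other")


def is_nan(x: float) -> bool:
    """True for the :data:`NO_PATHS` sentinel."""
    return isinstance(x, float) and math.isnan(x)
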