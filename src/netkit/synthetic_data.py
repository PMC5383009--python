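"""Synthetic benchmark data with known ground truth.

Everything the analysis pipeline consumes can be generated here offline:
scale-free interaction networks (preferential attachment, optionally a
configuration model with a target exponent), planted-partition graphs for
cluster-recovery benchmarks, protein→term annotation tables with planted
over-represented terms, and PSI-MITAB 2.5 files salted with a known number of
removable contaminant rows (non-human, chemical, self-loop, duplicate).

Contaminant classes are constructed pairwise disjoint — a non-human row is
never also a self-loop — so the curation filters' expected removal counts are
exact, and ``write_mitab`` returns the :class:`~netkit.mitab_io.FilterReport`
the parser is expected to reproduce.  Fixed seeds give byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegeneratePlantingError, EmptyInputError, InvalidParametersError
from .graph_core import Network, new_network

HUMAN_TAXON = 9606

#: Placeholder CV terms for the MITAB columns the curation filters never read.
_MITAB_FILLER = {
    "alias": "-",
    "method": 'psi-mi:"MI:0018"(two hybrid)',
    "author": "synthetic et al. (2016)",
    "pub": "pubmed:00000000",
    "itype": 'psi-mi:"MI:0915"(physical association)',
    "source": 'psi-mi:"MI:0469"(IntAct)',
    "iid": "intact:EBI-0000000",
    "conf": "-",
}


@dataclass
class ContaminationSpec:
    """How many removable rows of each class to inject into a MITAB file."""

    n_nonhuman_rows: int = 0
    n_chemical_rows: int = 0
    n_selfloop_rows: int = 0
    n_duplicate_rows: int = 0
    foreign_taxon_id: int = 10090

    def __post_init__(self) -> None:
        for name in ("n_nonhuman_rows", "n_chemical_rows", "n_selfloop_rows", "n_duplicate_rows"):
            if getattr(self, name) < 0:
                raise InvalidParametersError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return (
            self.n_nonhuman_rows
            + self.n_chemical_rows
            + self.n_selfloop_rows
            + self.n_duplicate_rows
        )


@dataclass
class PlantedGroundTruth:
    """What the generator planted, for later recovery checks."""

    module_assignment: dict[str, str] = field(default_factory=dict)
    enriched_terms: list[tuple[str, str, float]] = field(default_factory=list)
    seed_accessions: list[str] = field(default_factory=list)
    generator_seed: int = 0

    def __post_init__(self) -> None:
        modules = set(self.module_assignment.values())
        for term, module, _rate in self.enriched_terms:
            if module not in modules:
                raise InvalidParametersError(
                    f"enriched term {term!r} names unknown module {module!r}"
                )


def _accession(i: int) -> str:
    return f"S{i:05d}"


def generate_scale_free(
    n: int,
    edges_per_node: int,
    seed: int,
    *,
    model: str = "preferential_attachment",
    gamma: float = 2.5,
) -> Network:
    """A connected heavy-tailed network on synthetic accessions.

    The default preferential-attachment construction adds nodes one at a time,
    each wiring ``edges_per_node`` edges to existing nodes with probability
    proportional to degree; it yields exactly ``(n - edges_per_node) *
    edges_per_node`` edges and is always connected, mirroring the giant
    connected component the seed-expansion procedure produces on real data.
    ``model="configuration"`` instead samples a degree sequence from a bounded
    discrete power law with exponent ``gamma`` and wires a simple graph from
    it (connectivity not guaranteed) — useful for exponent-recovery tests.
    """
    if n <= edges_per_node:
        raise InvalidParametersError(f"need n > edges_per_node, got n={n}, m={edges_per_node}")
    if edges_per_node < 1:
        raise InvalidParametersError("edges_per_node must be >= 1")
    if model == "preferential_attachment":
        g = nx.barabasi_albert_graph(n, edges_per_node, seed=seed)
    elif model == "configuration":
        rng = np.random.default_rng(seed)
        ks = sample_power_law(gamma, n, k_min=edges_per_node, k_max=max(n // 10, edges_per_node + 1), rng=rng)
        if ks.sum() % 2:
            ks[0] += 1
        g = nx.Graph(nx.configuration_model(ks.tolist(), seed=seed))
        g.remove_edges_from(nx.selfloop_edges(g))
    else:
        raise InvalidParametersError(f"unknown model {model!r}")
    mapping = {v: _accession(v) for v in g.nodes}
    out = new_network()
    out.add_nodes_from(sorted(mapping.values()))
    out.add_edges_from(
        sorted(tuple(sorted((mapping[u], mapping[v]))) for u, v in g.edges)
    )
    for v in out.nodes:
        out.nodes[v].setdefault("category", "other")
        out.nodes[v].setdefault("roles", set())
    return out


def sample_power_law(
    gamma: float, size: int, *, k_min: int = 1, k_max: int = 50, rng: np.random.Generator
) -> np.ndarray:
    """Sample integers from an exact bounded discrete power law p(k) ∝ k^-gamma."""
    ks = np.arange(k_min, k_max + 1)
    p = ks.astype(float) ** (-gamma)
    p /= p.sum()
    return rng.choice(ks, size=size, p=p)


def generate_planted_partition(
    module_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[Network, PlantedGroundTruth]:
    """Planted-partition graph: within-module edges at ``p_in``, between at ``p_out``."""
    if not (0 <= p_out < p_in <= 1):
        raise DegeneratePlantingError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if not module_sizes or any(s < 1 for s in module_sizes):
        raise InvalidParametersError("module_sizes must be positive counts")
    rng = np.random.default_rng(seed)
    nodes: list[str] = []
    assignment: dict[str, str] = {}
    idx = 0
    for mi, size in enumerate(module_sizes):
        label = f"M{mi}"
        for _ in range(size):
            acc = _accession(idx)
            nodes.append(acc)
            assignment[acc] = label
            idx += 1
    g = new_network(nodes=nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            p = p_in if assignment[u] == assignment[v] else p_out
            if p > 0 and rng.random() < p:
                g.add_edge(u, v)
    truth = PlantedGroundTruth(
        module_assignment=assignment,
        seed_accessions=sorted(nodes),
        generator_seed=seed,
    )
    return g, truth


def generate_annotations(
    network: Network,
    n_terms: int,
    background_rate: float,
    ground_truth: PlantedGroundTruth | None,
    enriched_rate: float,
    seed: int,
    *,
    n_enriched_per_module: int = 1,
) -> pd.DataFrame:
    """Protein→term annotation table with planted over-represented terms.

    Every (protein, term) pair is annotated independently at
    ``background_rate``, except pairs where the term is planted on the
    protein's module, which use ``enriched_rate``.  Planted (term, module,
    rate) triples are appended to ``ground_truth.enriched_terms``.  Returns a
    two-column DataFrame (``accession``, ``term``).
    """
    if network.number_of_nodes() == 0:
        raise EmptyInputError("cannot annotate an empty network")
    if not (0 <= background_rate < enriched_rate <= 1):
        raise InvalidParametersError(
            f"need 0 <= background_rate < enriched_rate <= 1, got "
            f"{background_rate}, {enriched_rate}"
        )
    rng = np.random.default_rng(seed)
    terms = [f"T{t:04d}" for t in range(n_terms)]
    planted: dict[tuple[str, str], float] = {}
    if ground_truth is not None and ground_truth.module_assignment:
        modules = sorted(set(ground_truth.module_assignment.values()))
        ti = 0
        for module in modules:
            for _ in range(n_enriched_per_module):
                if ti >= len(terms):
                    break
                planted[(terms[ti], module)] = enriched_rate
                ground_truth.enriched_terms.append((terms[ti], module, enriched_rate))
                ti += 1
    rows: list[tuple[str, str]] = []
    for acc in sorted(network.nodes):
        module = ground_truth.module_assignment.get(acc) if ground_truth else None
        for term in terms:
            rate = planted.get((term, module), background_rate) if module else background_rate
            if rate > 0 and rng.random() < rate:
                rows.append((acc, term))
    return pd.DataFrame(rows, columns=["accession", "term"])


def _mitab_row(
    id_a: str,
    id_b: str,
    taxon_a: str,
    taxon_b: str,
) -> str:
    f = _MITAB_FILLER
    cols = [
        id_a,
        id_b,
        "-",
        "-",
        f["alias"],
        f["alias"],
        f["method"],
        f["author"],
        f["pub"],
        taxon_a,
        taxon_b,
        f["itype"],
        f["source"],
        f["iid"],
        f["conf"],
    ]
    return "\t".join(cols)


_MITAB_HEADER = (
    "#ID(s) interactor A\tID(s) interactor B\tAlt. ID(s) interactor A\t"
    "Alt. ID(s) interactor B\tAlias(es) interactor A\tAlias(es) interactor B\t"
    "Interaction detection method(s)\tPublication 1st author(s)\t"
    "Publication Identifier(s)\tTaxid interactor A\tTaxid interactor B\t"
    "Interaction type(s)\tSource database(s)\tInteraction identifier(s)\t"
    "Confidence value(s)"
)


def write_mitab(
    network: Network,
    contamination: ContaminationSpec,
    seed: int,
    path: str | Path,
):
    """Write the network as a PSI-MITAB 2.5 file with injected contaminants.

    One clean row per edge (both interactors ``uniprotkb:`` accessions,
    ``taxid:9606``); contaminant rows per the spec, at seeded shuffled
    positions.  Returns the FilterReport the curation filters are expected to
    produce, assuming assembly is run with a seed list covering the clean
    network (the generator's ground-truth seed list is all clean accessions).
    """
    from .mitab_io import FilterReport  # local import: avoid cycle

    if network.number_of_nodes() == 0:
        raise EmptyInputError("cannot write an empty network")
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in network.edges)
    nodes = sorted(network.nodes)
    human = f"taxid:{HUMAN_TAXON}(human)"
    foreign = f"taxid:{contamination.foreign_taxon_id}(foreign)"
    rows: list[str] = [
        _mitab_row(f"uniprotkb:{a}", f"uniprotkb:{b}", human, human) for a, b in edges
    ]
    # non-human rows: fresh foreign accessions, foreign taxa on both sides
    for i in range(contamination.n_nonhuman_rows):
        rows.append(
            _mitab_row(f"uniprotkb:X{2*i:05d}", f"uniprotkb:X{2*i+1:05d}", foreign, foreign)
        )
    # chemical rows: human taxa (keeps the class disjoint from non-human)
    for i in range(contamination.n_chemical_rows):
        rows.append(
            _mitab_row(f"uniprotkb:{nodes[i % len(nodes)]}", f"chebi:CHEBI:{15000 + i}", human, human)
        )
    # self-loops on fresh accessions: these nodes exist only in self
    # interactions and must be absent from the assembled network
    for i in range(contamination.n_selfloop_rows):
        acc = f"L{i:05d}"
        rows.append(_mitab_row(f"uniprotkb:{acc}", f"uniprotkb:{acc}", human, human))
    # duplicates of existing clean edges, in swapped column order for odd i
    pyrng = random.Random(seed)
    for i in range(contamination.n_duplicate_rows):
        a, b = edges[pyrng.randrange(len(edges))]
        if i % 2:
            a, b = b, a
        rows.append(_mitab_row(f"uniprotkb:{a}", f"uniprotkb:{b}", human, human))
    pyrng.shuffle(rows)
    path.write_text(_MITAB_HEADER + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
    return FilterReport(
        rows_read=len(rows),
        rows_nonhuman_removed=contamination.n_nonhuman_rows,
        rows_nonprotein_removed=contamination.n_chemical_rows,
        selfloops_removed=contamination.n_selfloop_rows,
        duplicates_removed=contamination.n_duplicate_rows,
        selfonly_nodes_removed=contamination.n_selfloop_rows,
        nodes_after_seed_step=len(nodes),
        edges_after_seed_step=len(edges),
        nodes_final=len(nodes),
        edges_final=len(edges),
    )
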