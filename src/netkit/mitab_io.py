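"""PSI-MITAB 2.5 parsing, curation filters, and seed-expanded network assembly.

The curation protocol mirrors the way interactome studies clean a raw
database export before graph analysis:

1. parse the tab-delimited MITAB 2.5 file (15 columns, ``-`` for missing);
2. drop rows that are not human–human (both taxa must equal the human
   taxon id) and rows involving non-protein interactors (identifier
   namespace other than ``uniprotkb``, e.g. ``chebi:`` chemicals);
3. drop self-loops and collapse duplicate rows (including swapped column
   order) onto canonical unordered accession pairs;
4. seed-expand: keep edges touching at least one seed protein, then add all
   edges among the nodes so collected.  Nodes whose only rows were
   self-interactions never enter the network.

A row failing several filters is counted once, in the first failing class
(non-human → non-protein → self-loop → duplicate), so the removal accounting
is unambiguous and order-stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConflictingCategoryError, EmptyInputError, EmptyNetworkError
from .graph_core import Network, new_network

logger = logging.getLogger(__name__)

HUMAN_TAXON = 9606
PROTEIN_NAMESPACE = "uniprotkb"


@dataclass
class InteractionRecord:
    """One parsed MITAB row (identifiers keep their namespace prefix)."""

    id_a: str
    id_b: str
    taxon_a: int | None
    taxon_b: int | None
    type_a: str | None
    type_b: str | None
    source_line: int

    @property
    def namespace_a(self) -> str:
        return self.id_a.split(":", 1)[0].lower()

    @property
    def namespace_b(self) -> str:
        return self.id_b.split(":", 1)[0].lower()

    @property
    def accession_a(self) -> str:
        return self.id_a.split(":", 1)[1] if ":" in self.id_a else self.id_a

    @property
    def accession_b(self) -> str:
        return self.id_b.split(":", 1)[1] if ":" in self.id_b else self.id_b


@dataclass
class FilterReport:
    """Row/edge accounting across the curation and assembly steps."""

    rows_read: int = 0
    rows_malformed: int = 0
    rows_nonhuman_removed: int = 0
    rows_nonprotein_removed: int = 0
    selfloops_removed: int = 0
    duplicates_removed: int = 0
    selfonly_nodes_removed: int = 0
    nodes_after_seed_step: int = 0
    edges_after_seed_step: int = 0
    nodes_final: int = 0
    edges_final: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_identifier(field: str, *, collapse_isoforms: bool) -> str:
    """First alternative of a MITAB ID column, isoform suffix collapsed."""
    first = field.split("|", 1)[0].strip()
    if collapse_isoforms and first.lower().startswith(PROTEIN_NAMESPACE + ":"):
        ns, acc = first.split(":", 1)
        acc = acc.split("-", 1)[0]
        first = f"{ns}:{acc}"
    return first


def _parse_taxon(field: str) -> int | None:
    """Integer taxon id from e.g. ``taxid:9606(human)``; None when missing."""
    field = field.split("|", 1)[0].strip()
    if not field or field == "-":
        return None
    if field.lower().startswith("taxid:"):
        field = field[len("taxid:"):]
    num = field.split("(", 1)[0].strip()
    try:
        return int(num)
    except ValueError:
        return None


def _parse_cv(field: str) -> str | None:
    field = field.strip()
    return None if not field or field == "-" else field


def parse_mitab(path: str | Path, *, collapse_isoforms: bool = True) -> list[InteractionRecord]:
    """Parse a MITAB 2.5 file into interaction records.

    Rows with fewer than 15 columns are skipped with a warning; interactor
    types are read from columns 21/22 when a wider (2.7-style) row provides
    them.  An empty file yields an empty list and an ``empty-input`` warning.
    By default isoform suffixes (``P05067-2``) are collapsed to the parent
    accession, since interactome node counts are per protein precursor.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    n_malformed = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                n_malformed += 1
                logger.warning("skipping malformed row %d (%d columns)", lineno, len(cols))
                continue
            records.append(
                InteractionRecord(
                    id_a=_parse_identifier(cols[0], collapse_isoforms=collapse_isoforms),
                    id_b=_parse_identifier(cols[1], collapse_isoforms=collapse_isoforms),
                    taxon_a=_parse_taxon(cols[9]),
                    taxon_b=_parse_taxon(cols[10]),
                    type_a=_parse_cv(cols[20]) if len(cols) > 20 else None,
                    type_b=_parse_cv(cols[21]) if len(cols) > 21 else None,
                    source_line=lineno,
                )
            )
    if not records:
        warnings.warn(f"empty-input: no data rows in {path}", stacklevel=2)
    last_malformed_counts[str(path)] = n_malformed
    return records


#: malformed-row count per file from the most recent parse (advisory)
last_malformed_counts: dict[str, int] = {}


def filter_records(
    records: Iterable[InteractionRecord], human_taxon: int = HUMAN_TAXON
) -> tuple[list[InteractionRecord], FilterReport]:
    """Keep human–human protein–protein rows; tally removals per class.

    A row is non-human unless *both* taxa equal ``human_taxon`` (mixed-taxon
    and missing-taxon rows are removed here); of the survivors, a row is
    non-protein unless both identifiers are in the ``uniprotkb`` namespace.
    """
    records = list(records)
    report = FilterReport(rows_read=len(records))
    kept: list[InteractionRecord] = []
    for rec in records:
        if rec.taxon_a != human_taxon or rec.taxon_b != human_taxon:
            report.rows_nonhuman_removed += 1
            continue
        if rec.namespace_a != PROTEIN_NAMESPACE or rec.namespace_b != PROTEIN_NAMESPACE:
            report.rows_nonprotein_removed += 1
            continue
        kept.append(rec)
    return kept, report


def dedupe_and_deloop(
    records: Iterable[InteractionRecord], report: FilterReport | None = None
) -> tuple[list[tuple[str, str]], FilterReport]:
    """Canonical unordered edge set; self-pairs and repeats removed and counted.

    Also counts nodes that appeared *only* in self-interaction rows (they can
    never enter an assembled network).
    """
    report = report or FilterReport()
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    selfloop_nodes: set[str] = set()
    edge_nodes: set[str] = set()
    for rec in records:
        a, b = rec.accession_a, rec.accession_b
        if a == b:
            report.selfloops_removed += 1
            selfloop_nodes.add(a)
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            report.duplicates_removed += 1
            continue
        seen.add(key)
        edges.append(key)
        edge_nodes.update(key)
    report.selfonly_nodes_removed = len(selfloop_nodes - edge_nodes)
    return sorted(edges), report


def assemble_network(
    edges: Iterable[tuple[str, str]],
    seeds: Iterable[str],
    report: FilterReport | None = None,
) -> tuple[Network, FilterReport]:
    """Seed-expand an edge set into the analysis network.

    Step 1 keeps edges incident to at least one seed, defining the node set
    V1 (matched seeds plus their partners).  Step 2 additionally keeps every
    edge with both endpoints in V1.  The result is a simple undirected graph.
    """
    report = report or FilterReport()
    seeds = set(seeds)
    if not seeds:
        raise EmptyInputError("seed list is empty")
    edges = sorted(set(tuple(sorted(e)) for e in edges))
    step1 = [e for e in edges if e[0] in seeds or e[1] in seeds]
    if not step1:
        raise EmptyNetworkError("no seed protein matched by any edge")
    v1: set[str] = set()
    for a, b in step1:
        v1.update((a, b))
    report.nodes_after_seed_step = len(v1)
    report.edges_after_seed_step = len(step1)
    final_edges = [e for e in edges if e[0] in v1 and e[1] in v1]
    g = new_network(final_edges)
    report.nodes_final = g.number_of_nodes()
    report.edges_final = g.number_of_edges()
    return g, report


def label_nodes(network: Network, categories: Mapping[str, str]) -> Network:
    """Attach amyloid categories to nodes; unlisted nodes become ``"other"``.

    ``categories`` maps accession → one of ``in_vivo_amyloid``,
    ``in_vitro_amyloid``, ``amyloid_related``.
    """
    for v in network.nodes:
        network.nodes[v]["category"] = categories.get(v, "other")
        network.nodes[v].setdefault("roles", set())
    return network


def merge_category_tables(*tables: Mapping[str, str]) -> dict[str, str]:
    """Merge accession→category maps, refusing conflicting assignments."""
    merged: dict[str, str] = {}
    for table in tables:
        for acc, cat in table.items():
            if acc in merged and merged[acc] != cat:
                raise ConflictingCategoryError(
                    f"{acc} listed as both {merged[acc]} and {cat}"
                )
            merged[acc] = cat
    return merged


def run_curation(
    path: str | Path,
    seeds: Iterable[str],
    *,
    human_taxon: int = HUMAN_TAXON,
    collapse_isoforms: bool = True,
) -> tuple[Network, FilterReport]:
    """parse → filter → dedupe/deloop → assemble, in one call."""
    records = parse_mitab(path, collapse_isoforms=collapse_isoforms)
    kept, report = filter_records(records, human_taxon=human_taxon)
    edges, report = dedupe_and_deloop(kept, report)
    return assemble_network(edges, seeds, report)


# ---------------------------------------------------------------------------
# Packaged seed fixtures: the 28 in vivo amyloid precursors and the 13
# in vitro / amyloid-related proteins, as (name, abbreviation, accession).
# ---------------------------------------------------------------------------

def _load_table(filename: str) -> list[tuple[str, str, str, str]]:
    text = resources.files("netkit.data").joinpath(filename).read_text(encoding="utf-8")
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, abbrev, accession, category = line.split("\t")
        rows.append((name, abbrev, accession, category))
    return rows


def load_seed_proteins() -> list[tuple[str, str, str, str]]:
    """The 28 in vivo amyloid-forming precursor proteins (the seed dataset)."""
    return _load_table("invivo_seeds.tsv")


def load_related_proteins() -> list[tuple[str, str, str, str]]:
    """The 13 in vitro amyloid-forming / amyloid-related proteins."""
    return _load_table("related_proteins.tsv")


def default_categories() -> dict[str, str]:
    """accession → category map for every packaged fixture protein."""
    table: dict[str, str] = {}
    for _, _, acc, cat in load_seed_proteins() + load_related_proteins():
        table[acc] = cat
    return merge_category_tables(table)


def seed_accessions() -> list[str]:
    """Accessions of the 28 in vivo seed proteins."""
    return [acc for _, _, acc, _ in load_seed_proteins()]


def write_edge_list(network: Network, path: str | Path) -> None:
    """Two-column TSV of canonical edges."""
    lines = [f"{a}\t{b}" for a, b in sorted(tuple(sorted(e)) for e in network.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_edge_list(path: str | Path) -> Network:
    edges = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line and not line.startswith("#"):
            a, b = line.split("\t")[:2]
            edges.append((a, b))
    return new_network(edges)
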