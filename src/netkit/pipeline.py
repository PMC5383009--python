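"""End-to-end orchestration: assemble → label → topology → robustness →
cluster → enrich, from one configuration, with machine-readable outputs.

Every stochastic stage (null model, failure trajectories) takes its seed
from the config — there is no wall-clock seeding, so a re-run with the same
config reproduces every deterministic section bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import yaml

from . import __version__, enrichment, graph_core, mcl_clustering, mitab_io, robustness, topology
from .errors import EmptyInputError, InvalidFormatError, StageError
from .graph_core import Network


@dataclass
class PipelineConfig:
    """One run of the full study."""

    mitab_path: str
    seed_list_path: str | None = None
    category_table_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    annotation_parent_path: str | None = None
    taxon: int = 9606
    topn: int = 20
    inflation: float = 1.8
    min_cluster_size: int = 3
    alpha: float = 0.05
    min_drivers: int = 3
    null_replicates: int = 100
    run_lethality: bool = True
    lethality_max_fraction: float = 0.2
    lethality_n_failure_seeds: int = 20
    rng_seed: int = 0
    keep_isoforms: bool = False
    output_dir: str = "netkit_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    filter_report: mitab_io.FilterReport
    topology_summary: graph_core.TopologySummary
    degree_fit: topology.PowerLawFit | None
    ck_fit: topology.PowerLawFit | None
    null_comparison: topology.NullModelComparison
    centrality_call: topology.CentralityCall
    trajectories: list[robustness.RobustnessTrajectory]
    cluster_set: mcl_clustering.ClusterSet
    network_enrichment: list[enrichment.EnrichmentResult]
    cluster_enrichment: dict[int, list[enrichment.EnrichmentResult]]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        def fits(f):
            return None if f is None else dataclasses.asdict(f)

        return {
            "filter_report": self.filter_report.to_dict(),
            "topology": self.topology_summary.to_dict(),
            "degree_fit": fits(self.degree_fit),
            "ck_fit": fits(self.ck_fit),
            "null_comparison": dataclasses.asdict(self.null_comparison),
            "hubs": self.centrality_call.hubs,
            "bottlenecks": self.centrality_call.bottlenecks,
            "hub_bottleneck_overlap": self.centrality_call.both,
            "trajectories": [dataclasses.asdict(t) for t in self.trajectories],
            "cluster_sizes": self.cluster_set.sizes(),
            "mcl_converged": self.cluster_set.converged,
            "network_enrichment_significant": [
                r.term for r in self.network_enrichment if r.significant
            ],
            "cluster_enrichment_significant": {
                str(cid): [r.term for r in results if r.significant]
                for cid, results in self.cluster_enrichment.items()
            },
            "provenance": self.provenance,
        }


def export_network(network: Network, fmt: str, path: str | Path) -> None:
    """Write a network as SIF, GraphML or edge-list TSV.

    GraphML carries node attributes (category, roles, cluster id) and is
    round-trippable through :func:`import_network`.
    """
    if network.number_of_nodes() == 0:
        raise EmptyInputError("cannot export an empty network")
    path = Path(path)
    if fmt == "tsv":
        mitab_io.write_edge_list(network, path)
    elif fmt == "sif":
        lines = [
            f"{a}\tinteracts\t{b}"
            for a, b in sorted(tuple(sorted(e)) for e in network.edges)
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "graphml":
        g = network.copy()
        for v in g.nodes:
            roles = g.nodes[v].get("roles", set())
            g.nodes[v]["roles"] = ",".join(sorted(roles)) if isinstance(roles, set) else str(roles)
        nx.write_graphml(g, path)
    else:
        raise InvalidFormatError(f"unknown format {fmt!r}; expected sif, graphml or tsv")


def import_network(path: str | Path, fmt: str | None = None) -> Network:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    fmt = fmt or {".sif": "sif", ".graphml": "graphml"}.get(path.suffix, "tsv")
    if fmt == "graphml":
        g = nx.Graph(nx.read_graphml(path))
        for v in g.nodes:
            roles = g.nodes[v].get("roles", "")
            g.nodes[v]["roles"] = set(roles.split(",")) - {""} if isinstance(roles, str) else roles
            g.nodes[v].setdefault("category", "other")
        return g
    edges = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        edges.append((cols[0], cols[-1]) if fmt == "sif" else (cols[0], cols[1]))
    return graph_core.new_network(edges)


def _read_seed_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order and write artifacts to the output directory.

    Stage failures raise :class:`StageError` tagged with the stage name;
    artifacts written before the failure are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- assemble ---------------------------------------------------------
    try:
        seeds = (
            _read_seed_list(config.seed_list_path)
            if config.seed_list_path
            else mitab_io.seed_accessions()
        )
        network, filter_report = mitab_io.run_curation(
            config.mitab_path,
            seeds,
            human_taxon=config.taxon,
            collapse_isoforms=not config.keep_isoforms,
        )
    except Exception as exc:  # noqa: BLE001 - tag and re-raise per contract
        raise StageError("assemble", str(exc)) from exc

    # --- label ------------------------------------------------------------
    try:
        if config.category_table_paths:
            tables = []
            for p in config.category_table_paths:
                table: dict[str, str] = {}
                for line in Path(p).read_text(encoding="utf-8").splitlines():
                    if line and not line.startswith("#"):
                        cols = line.split("\t")
                        table[cols[-2]] = cols[-1]
                tables.append(table)
            categories = mitab_io.merge_category_tables(*tables)
        else:
            categories = mitab_io.default_categories()
        mitab_io.label_nodes(network, categories)
    except Exception as exc:  # noqa: BLE001
        raise StageError("label", str(exc)) from exc

    # --- topology ---------------------------------------------------------
    try:
        summary = graph_core.summarize(network)
        try:
            degree_fit = topology.fit_power_law(
                {float(k): float(c) for k, c in summary.degree_histogram.items()}
            )
        except Exception:
            degree_fit = None
        try:
            ck_fit = topology.ck_scaling(network)
        except Exception:
            ck_fit = None
        null_cmp = topology.null_model_comparison(
            summary.n,
            summary.m,
            replicates=config.null_replicates,
            seed=config.rng_seed,
            cc_observed=summary.cc,
            cpl_observed=summary.cpl,
        )
        call = topology.call_hubs_bottlenecks(network, N=config.topn)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("topology", str(exc)) from exc

    # --- robustness -------------------------------------------------------
    trajectories: list[robustness.RobustnessTrajectory] = []
    if config.run_lethality:
        try:
            failure_seeds = [config.rng_seed + i for i in range(config.lethality_n_failure_seeds)]
            trajectories = [
                robustness.lethality_test(
                    network, "failure", config.lethality_max_fraction, seeds=failure_seeds
                ),
                robustness.lethality_test(network, "degree_attack", config.lethality_max_fraction),
                robustness.lethality_test(
                    network, "betweenness_attack", config.lethality_max_fraction
                ),
            ]
        except Exception as exc:  # noqa: BLE001
            raise StageError("lethality", str(exc)) from exc

    # --- cluster ----------------------------------------------------------
    try:
        params = mcl_clustering.MCLParams(inflation=config.inflation)
        cluster_set = mcl_clustering.mcl_cluster(network, params)
        kept, _dropped = mcl_clustering.filter_clusters(cluster_set, config.min_cluster_size)
    except Exception as exc:  # noqa: BLE001
        raise StageError("cluster", str(exc)) from exc

    # --- enrich -----------------------------------------------------------
    network_results: list[enrichment.EnrichmentResult] = []
    cluster_results: dict[int, list[enrichment.EnrichmentResult]] = {}
    if config.annotation_path:
        try:
            ann = enrichment.read_annotations(
                config.annotation_path, config.annotation_parent_path
            )
            if ann.term_parents:
                ann = enrichment.propagate_annotations(ann)
            background = sorted(set(network.nodes) & ann.proteins())
            if background:
                annotated_nodes = set(background)
                network_results = enrichment.enrich(
                    annotated_nodes, ann, background, config.alpha, config.min_drivers
                )
                for cid, cluster in enumerate(kept):
                    study = sorted(cluster & annotated_nodes)
                    if study:
                        cluster_results[cid] = enrichment.enrich(
                            study, ann, background, config.alpha, config.min_drivers
                        )
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", str(exc)) from exc

    provenance = {
        "netkit_version": __version__,
        "config": config.to_dict(),
        "rng_seed": config.rng_seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    bundle = ReportBundle(
        filter_report=filter_report,
        topology_summary=summary,
        degree_fit=degree_fit,
        ck_fit=ck_fit,
        null_comparison=null_cmp,
        centrality_call=call,
        trajectories=trajectories,
        cluster_set=cluster_set,
        network_enrichment=network_results,
        cluster_enrichment=cluster_results,
        provenance=provenance,
    )

    # --- write artifacts ---------------------------------------------------
    try:
        labels = cluster_set.labels()
        for v in network.nodes:
            network.nodes[v]["cluster_id"] = labels.get(v, -1)
        export_network(network, "graphml", out / "network.graphml")
        export_network(network, "tsv", out / "network.tsv")
        export_network(network, "sif", out / "network.sif")
        cluster_set.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        if trajectories:
            table, areas = robustness.attack_failure_report(trajectories)
            table.to_csv(out / "lethality.tsv", sep="\t", index=False)
            provenance["lethality_area_vs_failure"] = areas
        if network_results:
            enrichment.results_to_frame(network_results).to_csv(
                out / "enrichment_network.tsv", sep="\t", index=False
            )
        for cid, results in cluster_results.items():
            enrichment.results_to_frame(results).to_csv(
                out / f"enrichment_cluster{cid}.tsv", sep="\t", index=False
            )
        (out / "report.json").write_text(
            json.dumps(bundle.to_dict(), indent=2, default=_json_default), encoding="utf-8"
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("write", str(exc)) from exc
    return bundle


def _json_default(obj):
    import math

    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, set):
        return sorted(obj)
    return str(obj)
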