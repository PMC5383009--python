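"""Lethality testing: CPL under random failure versus targeted attack.

Nodes are removed one at a time — uniformly at random per seed ("failure"),
or in descending order of degree / betweenness centrality computed on the
intact network ("attacks", static ranking by default).  After each removal
the characteristic path length (over remaining connected pairs) and the
giant-component fraction are recorded.  Scale-free networks are expected to
tolerate failures but not attacks: targeted removal of hubs inflates the
CPL rapidly while random removals barely move it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graph_core, topology
from .errors import (
    IncompatibleTrajectoriesError,
    InvalidModeError,
    InvalidParametersError,
    MissingSeedsError,
)
from .graph_core import NO_PATHS, Network

MODES = ("failure", "degree_attack", "betweenness_attack")


@dataclass
class RobustnessTrajectory:
    """One removal trajectory (failure trajectories are averaged over seeds)."""

    mode: str
    removed_fraction: list[float]
    cpl: list[float]
    giant_fraction: list[float]
    cpl_sd: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    ranking_policy: str = "static"
    initial_n: int = 0

    def to_frame(self) -> pd.DataFrame:
        data = {
            "mode": self.mode,
            "removed_fraction": self.removed_fraction,
            "cpl": self.cpl,
            "giant_fraction": self.giant_fraction,
        }
        if self.cpl_sd:
            data["cpl_sd"] = self.cpl_sd
        return pd.DataFrame(data)


def _attack_order(network: Network, mode: str) -> list[str]:
    if mode == "degree_attack":
        score = {v: k for v, k in network.degree()}
    else:
        score, _ = graph_core.betweenness(network)
    return sorted(network.nodes, key=lambda v: (-score[v], v))


def _single_run(
    network: Network, order: list[str], n_remove: int, step: int
) -> tuple[list[float], list[float], list[float]]:
    """Remove ``order[:n_remove]`` in chunks of ``step``, recording after each chunk.

    Index 0 is the intact network.  Truncates at the no-paths sentinel.
    """
    g = network.copy()
    n0 = network.number_of_nodes()
    fractions = [0.0]
    cpls = [graph_core.characteristic_path_length(g)]
    giants = [len(graph_core.components(g)[0]) / n0 if g.number_of_nodes() else 0.0]
    removed = 0
    for start in range(0, n_remove, step):
        chunk = order[start : min(start + step, n_remove)]
        g.remove_nodes_from(chunk)
        removed += len(chunk)
        cpl = graph_core.characteristic_path_length(g)
        comps = graph_core.components(g)
        fractions.append(removed / n0)
        cpls.append(cpl)
        giants.append(len(comps[0]) / n0 if comps else 0.0)
        if math.isnan(cpl):
            break  # no connected pair left; trajectory truncates at the sentinel
    return fractions, cpls, giants


def lethality_test(
    network: Network,
    mode: str,
    max_fraction: float = 0.2,
    step: int = 1,
    seeds: list[int] | None = None,
    ranking_policy: str = "static",
) -> RobustnessTrajectory:
    """Remove nodes gradually and track CPL and giant-component fraction.

    ``removed_fraction`` starts at 0 (intact network).  In failure mode the
    per-seed trajectories are averaged with a per-step standard deviation;
    seeds that hit the no-paths sentinel early stop contributing beyond it.
    With ``ranking_policy="recomputed"`` the attack re-ranks the remaining
    nodes after every removal instead of using the intact-network order.
    """
    if mode not in MODES:
        raise InvalidModeError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not (0 < max_fraction <= 1):
        raise InvalidParametersError("max_fraction must be in (0, 1]")
    if step < 1:
        raise InvalidParametersError("step must be >= 1 node")
    if graph_core.is_nan(graph_core.characteristic_path_length(network)):
        raise InvalidParametersError("initial network has no connected pair")
    n0 = network.number_of_nodes()
    n_remove = int(max_fraction * n0)

    if mode in ("degree_attack", "betweenness_attack"):
        if ranking_policy == "static":
            order = _attack_order(network, mode)
            fractions, cpls, giants = _single_run(network, order, n_remove, step)
        elif ranking_policy == "recomputed":
            g = network.copy()
            fractions = [0.0]
            cpls = [graph_core.characteristic_path_length(g)]
            giants = [len(graph_core.components(g)[0]) / n0]
            removed = 0
            while removed < n_remove:
                for _ in range(min(step, n_remove - removed)):
                    g.remove_node(_attack_order(g, mode)[0])
                    removed += 1
                cpl = graph_core.characteristic_path_length(g)
                comps = graph_core.components(g)
                fractions.append(removed / n0)
                cpls.append(cpl)
                giants.append(len(comps[0]) / n0 if comps else 0.0)
                if math.isnan(cpl):
                    break
        else:
            raise InvalidParametersError(f"unknown ranking_policy {ranking_policy!r}")
        return RobustnessTrajectory(
            mode=mode,
            removed_fraction=fractions,
            cpl=cpls,
            giant_fraction=giants,
            ranking_policy=ranking_policy,
            initial_n=n0,
        )

    # failure mode
    if not seeds:
        raise MissingSeedsError("failure mode requires at least one seed")
    runs_cpl, runs_giant = [], []
    fractions_longest: list[float] = [0.0]
    nodes_sorted = sorted(network.nodes)
    for s in seeds:
        rng = np.random.default_rng(s)
        order = [nodes_sorted[i] for i in rng.permutation(n0)]
        fr, cpls, giants = _single_run(network, order, n_remove, step)
        if len(fr) > len(fractions_longest):
            fractions_longest = fr
        runs_cpl.append(cpls)
        runs_giant.append(giants)
    length = max(len(r) for r in runs_cpl)
    cpl_mat = np.full((len(seeds), length), np.nan)
    giant_mat = np.full((len(seeds), length), np.nan)
    for i, (rc, rg) in enumerate(zip(runs_cpl, runs_giant)):
        cpl_mat[i, : len(rc)] = rc
        giant_mat[i, : len(rg)] = rg
    with np.errstate(invalid="ignore"):
        cpl_mean = np.nanmean(cpl_mat, axis=0)
        cpl_sd = np.nanstd(cpl_mat, axis=0)
        giant_mean = np.nanmean(giant_mat, axis=0)
    return RobustnessTrajectory(
        mode="failure",
        removed_fraction=fractions_longest,
        cpl=[float(x) for x in cpl_mean],
        giant_fraction=[float(x) for x in giant_mean],
        cpl_sd=[float(x) for x in cpl_sd],
        seeds=list(seeds),
        initial_n=n0,
    )


def attack_failure_report(
    trajectories: list[RobustnessTrajectory],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Align trajectories on removed fraction and compute area-between-curves.

    The area statistic for each mode is the trapezoidal integral of
    (mode CPL - baseline CPL) over the common removed-fraction range, with
    the failure trajectory as baseline when present (else the first
    trajectory).  Positive area for an attack means the attack inflated the
    CPL more than random failure — the lethality signature of a hub-dominated
    network.
    """
    if len(trajectories) < 2:
        raise InvalidParametersError("need >= 2 trajectories to compare")
    n0 = trajectories[0].initial_n
    if any(t.initial_n != n0 for t in trajectories):
        raise IncompatibleTrajectoriesError("trajectories come from different initial networks")
    baseline = next((t for t in trajectories if t.mode == "failure"), trajectories[0])
    n_common = min(len(t.cpl) for t in trajectories)
    fractions = baseline.removed_fraction[:n_common]
    table = pd.DataFrame({"removed_fraction": fractions})
    for t in trajectories:
        table[t.mode] = t.cpl[:n_common]
    areas: dict[str, float] = {}
    base = np.array(baseline.cpl[:n_common])
    for t in trajectories:
        if t is baseline:
            continue
        diff = np.array(t.cpl[:n_common]) - base
        ok = ~np.isnan(diff)
        areas[t.mode] = float(np.trapezoid(diff[ok], np.array(fractions)[ok])) if ok.sum() > 1 else 0.0
    return table, areas
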