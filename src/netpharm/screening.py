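"""Two-stage median-threshold hub screening.

Stage 1 ("hit hubs"): keep nodes of the intersection network whose degree
strictly exceeds twice the median degree (isolates included in the median).

Stage 2 ("core targets"): recompute all five topology metrics and keep nodes
that strictly and simultaneously exceed the median of every metric. By
default the stage-2 metrics and medians are taken on the hit-hub network
itself (``median_scope="stage"``); ``median_scope="intersection"`` instead
evaluates metrics and medians on the parent intersection network and applies
the cuts to hit-hub nodes.

Every stage returns the induced subgraph on the surviving nodes together
with the thresholds actually used, so strict exceedance is re-checkable from
the stored tables. An empty survivor set is a warning, not an error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import METRICS, compute_all
from .network import induced_subnetwork, intersect_networks

__all__ = [
    "median",
    "ThresholdSet",
    "ScreeningResult",
    "hit_hub_filter",
    "core_target_filter",
    "run_screening",
    "top_k_by_degree",
    "save_screening_result",
]

logger = logging.getLogger(__name__)


def median(values) -> float:
    """Plain median: middle order statistic, or mean of the two middle ones."""
    vals = list(values)
    if not vals:
        raise ValueError("median of an empty list is undefined")
    return float(np.median(vals))


@dataclass(frozen=True)
class ThresholdSet:
    """The five stage-2 cuts actually applied, plus how they were derived."""

    degree_cut: float
    closeness_cut: float
    betweenness_cut: float
    nc_cut: float
    lac_cut: float
    rule: str = "median"

    def as_dict(self) -> dict[str, float | str]:
        return {
            "degree_cut": self.degree_cut,
            "closeness_cut": self.closeness_cut,
            "betweenness_cut": self.betweenness_cut,
            "nc_cut": self.nc_cut,
            "lac_cut": self.lac_cut,
            "rule": self.rule,
        }

    def column_cuts(self) -> dict[str, float]:
        return {
            "degree": self.degree_cut,
            "betweenness": self.betweenness_cut,
            "closeness": self.closeness_cut,
            "neighborhood_connectivity": self.nc_cut,
            "lac": self.lac_cut,
        }


@dataclass
class ScreeningResult:
    """All stages of the cascade: networks, centrality tables, thresholds."""

    intersection: nx.Graph
    hit_hubs: nx.Graph
    hit_hub_threshold: float
    core: nx.Graph
    core_thresholds: ThresholdSet
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    median_scope: str = "stage"

    def stage_counts(self) -> dict[str, int]:
        return {
            "intersection_nodes": self.intersection.number_of_nodes(),
            "intersection_edges": self.intersection.number_of_edges(),
            "hit_hub_nodes": self.hit_hubs.number_of_nodes(),
            "hit_hub_edges": self.hit_hubs.number_of_edges(),
            "core_nodes": self.core.number_of_nodes(),
            "core_edges": self.core.number_of_edges(),
        }


def hit_hub_filter(net: nx.Graph) -> tuple[nx.Graph, float]:
    """Stage 1: nodes whose degree strictly exceeds 2x the median degree."""
    if net.number_of_nodes() == 0:
        return induced_subnetwork(net, set(), provenance="hit_hubs"), 0.0
    degrees = {v: net.degree(v) for v in sorted(net.nodes)}
    threshold = 2.0 * median(degrees.values())
    kept = {v for v, d in degrees.items() if d > threshold}
    if not kept:
        logger.warning("hit-hub filter removed every node (threshold %.6g)", threshold)
    return induced_subnetwork(net, kept, provenance="hit_hubs"), threshold


def _median_thresholds(table: pd.DataFrame, rule: str) -> ThresholdSet:
    return ThresholdSet(
        degree_cut=median(table["degree"]),
        closeness_cut=median(table["closeness"]),
        betweenness_cut=median(table["betweenness"]),
        nc_cut=median(table["neighborhood_connectivity"]),
        lac_cut=median(table["lac"]),
        rule=rule,
    )


def _survivors(table: pd.DataFrame, cuts: ThresholdSet, candidates=None) -> set[str]:
    mask = pd.Series(True, index=table.index)
    for col, cut in cuts.column_cuts().items():
        mask &= table[col] > cut
    kept = set(table.index[mask])
    if candidates is not None:
        kept &= set(candidates)
    return kept


def core_target_filter(net: nx.Graph) -> tuple[nx.Graph, ThresholdSet]:
    """Stage 2 on a single network: exceed the median of all five metrics."""
    if net.number_of_nodes() == 0:
        empty = induced_subnetwork(net, set(), provenance="core")
        return empty, ThresholdSet(0.0, 0.0, 0.0, 0.0, 0.0, rule="median")
    table = compute_all(net)
    cuts = _median_thresholds(table, rule="median")
    kept = _survivors(table, cuts)
    if not kept:
        logger.warning("core-target filter removed every node")
    return induced_subnetwork(net, kept, provenance="core"), cuts


def run_screening(
    drug_net: nx.Graph, disease_net: nx.Graph, median_scope: str = "stage"
) -> ScreeningResult:
    """Full cascade: intersect, hit-hub filter, five-metric core filter."""
    if median_scope not in ("stage", "intersection"):
        raise ValueError("median_scope must be 'stage' or 'intersection'")

    inter = intersect_networks(drug_net, disease_net)
    logger.info(
        "intersection network: %d nodes, %d edges",
        inter.number_of_nodes(), inter.number_of_edges(),
    )
    tables: dict[str, pd.DataFrame] = {}
    tables["intersection"] = compute_all(inter)

    hubs, hub_threshold = hit_hub_filter(inter)
    logger.info(
        "hit-hub network: %d nodes, %d edges (degree > %.6g)",
        hubs.number_of_nodes(), hubs.number_of_edges(), hub_threshold,
    )

    if median_scope == "stage":
        if hubs.number_of_nodes():
            stage_table = compute_all(hubs)
            cuts = _median_thresholds(stage_table, rule="median")
            kept = _survivors(stage_table, cuts)
        else:
            stage_table = tables["intersection"].iloc[0:0]
            cuts = ThresholdSet(0.0, 0.0, 0.0, 0.0, 0.0, rule="median")
            kept = set()
        tables["hit_hubs"] = stage_table
        core = induced_subnetwork(hubs, kept, provenance="core")
    else:
        stage_table = tables["intersection"]
        tables["hit_hubs"] = stage_table.loc[sorted(hubs.nodes)]
        if inter.number_of_nodes():
            cuts = _median_thresholds(stage_table, rule="median(intersection)")
            kept = _survivors(stage_table, cuts, candidates=hubs.nodes)
        else:
            cuts = ThresholdSet(0.0, 0.0, 0.0, 0.0, 0.0, rule="median(intersection)")
            kept = set()
        core = induced_subnetwork(hubs, kept, provenance="core")

    if core.number_of_nodes():
        tables["core"] = compute_all(core)
    else:
        tables["core"] = tables["intersection"].iloc[0:0]
        logger.warning("screening produced an empty core network")
    logger.info(
        "core network: %d nodes, %d edges", core.number_of_nodes(), core.number_of_edges()
    )

    return ScreeningResult(
        intersection=inter,
        hit_hubs=hubs,
        hit_hub_threshold=hub_threshold,
        core=core,
        core_thresholds=cuts,
        tables=tables,
        median_scope=median_scope,
    )


def top_k_by_degree(table: pd.DataFrame, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by degree, ties broken lexicographically by node id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table["degree"].items(), key=lambda kv: (-kv[1], kv[0]))
    return [(node, int(deg)) for node, deg in ranked[:k]]


def save_screening_result(result: ScreeningResult, outdir: str | Path) -> Path:
    """Write stage networks (TSV + GraphML), tables (TSV), and a JSON report."""
    from .io import write_centrality_table, write_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {
        "intersection": result.intersection,
        "hit_hubs": result.hit_hubs,
        "core": result.core,
    }
    for name, net in stages.items():
        write_network(net, outdir / f"{name}.tsv", dialect="tsv")
        write_network(net, outdir / f"{name}.graphml", dialect="graphml")
    for name, table in result.tables.items():
        write_centrality_table(table, outdir / f"{name}_centrality.tsv")
    report = {
        **result.stage_counts(),
        "hit_hub_degree_threshold": result.hit_hub_threshold,
        "core_thresholds": result.core_thresholds.as_dict(),
        "median_scope": result.median_scope,
        "core_targets": sorted(result.core.nodes),
    }
    report_path = outdir / "screening_report.json"
    report_path.write_text(json.dumps(report, indent=2) + "\n")
    return report_path
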