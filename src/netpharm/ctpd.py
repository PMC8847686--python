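"""Compound-target-pathway-disease (C-T-P-D) network assembly and export.

The network is tetrapartite: one compound node linked to every core target,
targets linked to the significant terms whose member sets contain them, and
every significant term linked to one disease node. Node size metadata
(``size_score``) is the node's degree divided by the maximum degree, so
visual size is proportional to degree.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import AnnotationDB, EnrichmentResult

__all__ = ["build_ctpd", "export_ctpd", "read_ctpd_graphml"]

logger = logging.getLogger(__name__)

LAYERS = ("compound", "target", "pathway", "disease")
_ADJACENT = {("compound", "target"), ("target", "pathway"), ("pathway", "disease")}


def build_ctpd(
    compound_id: str,
    targets,
    enrichment: list[EnrichmentResult],
    disease_id: str,
    db: AnnotationDB,
) -> nx.Graph:
    """Assemble the tetrapartite C-T-P-D graph.

    Edges: compound-target for every target; target-pathway for every
    (target, significant term) membership pair; pathway-disease for every
    significant term. With no significant terms the result degenerates to a
    compound-target star (logged as a warning).
    """
    targets = sorted(set(targets))
    if not targets:
        raise ValueError("targets must be non-empty")
    significant = [r for r in enrichment if r.significant]
    if not significant:
        logger.warning("no significant terms: C-T-P-D network has only compound-target edges")

    g = nx.Graph(compound=compound_id, disease=disease_id)
    g.add_node(compound_id, layer="compound")
    for t in targets:
        g.add_node(t, layer="target")
        g.add_edge(compound_id, t)
    if significant:
        g.add_node(disease_id, layer="disease")
    for r in sorted(significant, key=lambda r: r.term_id):
        g.add_node(r.term_id, layer="pathway")
        _, members = db.terms[r.term_id]
        for t in targets:
            if t in members:
                g.add_edge(t, r.term_id)
        g.add_edge(r.term_id, disease_id)

    _check_tetrapartite(g)
    max_deg = max(d for _, d in g.degree)
    for v in g.nodes:
        g.nodes[v]["degree"] = g.degree(v)
        g.nodes[v]["size_score"] = g.degree(v) / max_deg
    return g


def _check_tetrapartite(g: nx.Graph) -> None:
    for u, v in g.edges:
        pair = tuple(sorted((g.nodes[u]["layer"], g.nodes[v]["layer"])))
        if pair not in {tuple(sorted(p)) for p in _ADJACENT}:
            raise ValueError(f"edge {u}-{v} joins non-adjacent layers {pair}")


def export_ctpd(net: nx.Graph, path: str | Path, dialect: str = "graphml") -> None:
    """Write the network; ``graphml`` keeps node attributes in one file,
    ``tsv`` emits ``<path>.nodes.tsv`` and ``<path>.edges.tsv`` tables."""
    path = Path(path)
    if dialect == "graphml":
        nx.write_graphml(net, path)
    elif dialect == "tsv":
        nodes = pd.DataFrame(
            [
                {
                    "id": v,
                    "layer": net.nodes[v]["layer"],
                    "degree": net.nodes[v]["degree"],
                    "size_score": net.nodes[v]["size_score"],
                }
                for v in sorted(net.nodes)
            ],
            columns=["id", "layer", "degree", "size_score"],
        )
        edges = pd.DataFrame(
            sorted(tuple(sorted(e)) for e in net.edges), columns=["source", "target"]
        )
        edges["layer_pair"] = [
            "-".join(
                sorted(
                    (net.nodes[s]["layer"], net.nodes[t]["layer"]),
                    key=LAYERS.index,
                )
            )
            for s, t in zip(edges["source"], edges["target"])
        ] if len(edges) else []
        nodes.to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False)
        edges.to_csv(path.with_suffix(path.suffix + ".edges.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'graphml' or 'tsv'")


def read_ctpd_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(Path(path))
    out = nx.Graph(**g.graph)
    for v, data in g.nodes(data=True):
        out.add_node(
            str(v),
            layer=data["layer"],
            degree=int(data["degree"]),
            size_score=float(data["size_score"]),
        )
    out.add_edges_from((str(u), str(v)) for u, v in g.edges())
    return out
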