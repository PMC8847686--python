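"""Seeded PPI subnetwork construction and network intersection.

A seed network is the subgraph induced by a set of seed targets plus their
direct interactors in a reference interactome (one-hop expansion). The
intersection of the drug-side and disease-side seed networks — common nodes
and common edges, isolated nodes retained — is the universe the hub-screening
cascade operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

__all__ = ["SeedSet", "build_seed_network", "intersect_networks", "induced_subnetwork"]

logger = logging.getLogger(__name__)


class NoSeedsMappableError(ValueError):
    """No member of the seed set maps into the interactome."""


@dataclass(frozen=True)
class SeedSet:
    """A named set of seed-target identifiers (drug side or disease side)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError("seed set must be non-empty")
        for m in self.members:
            if not m or any(c.isspace() for c in m):
                raise ValueError(f"invalid seed identifier: {m!r}")


def build_seed_network(interactome: nx.Graph, seeds: SeedSet) -> nx.Graph:
    """Expand seed targets one hop into the interactome.

    Nodes are the seeds present in the interactome plus all their direct
    interactors; edges are every interactome edge with both endpoints in that
    node set (induced subgraph). Seeds absent from the interactome are logged
    and ignored; if none map, raises :class:`NoSeedsMappableError`.
    """
    present = seeds.members & set(interactome.nodes)
    missing = seeds.members - present
    if missing:
        logger.warning(
            "%d/%d %s seeds absent from interactome and ignored",
            len(missing), len(seeds.members), seeds.name,
        )
    if not present:
        raise NoSeedsMappableError("no seeds mappable into the interactome")

    node_set = set(present)
    for s in present:
        node_set.update(interactome.neighbors(s))
    sub = induced_subnetwork(interactome, node_set, provenance=seeds.name)
    logger.info(
        "%s seed network: %d nodes, %d edges (from %d mapped seeds)",
        seeds.name, sub.number_of_nodes(), sub.number_of_edges(), len(present),
    )
    return sub


def intersect_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Node-and-edge intersection of two networks (Merge-intersection semantics).

    Nodes present in both and edges present in both are kept; nodes left
    isolated by the edge intersection are retained so that downstream degree
    medians see them. An empty intersection is a legal, logged outcome.
    """
    nodes = set(a.nodes) & set(b.nodes)
    out = nx.Graph(provenance="intersection")
    out.add_nodes_from(sorted(nodes))
    for u, v in a.edges:
        if u in nodes and v in nodes and b.has_edge(u, v):
            out.add_edge(u, v)
    if out.number_of_nodes() == 0:
        logger.warning("network intersection is empty")
    return out


def induced_subnetwork(parent: nx.Graph, nodes, provenance: str = "subnetwork") -> nx.Graph:
    """Copy of the subgraph of ``parent`` induced by ``nodes``."""
    node_set = set(nodes)
    out = nx.Graph(provenance=provenance)
    out.add_nodes_from(sorted(node_set))
    out.add_edges_from(
        (u, v) for u, v in parent.edges if u in node_set and v in node_set
    )
    return out
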