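"""The five node-topology metrics the hub-screening cascade ranks on.

Conventions (chosen to match raw CytoNCA-style output scales):

* degree — number of distinct neighbours.
* betweenness — Brandes' algorithm, unnormalized, each unordered pair of
  distinct endpoints counted once; node pairs in different components
  contribute nothing.
* closeness — computed within connected components: for a node v in a
  component of size c >= 2, (c - 1) / sum of distances from v; values lie in
  (0, 1]; an isolated node scores 0.
* neighborhood connectivity — mean degree of a node's neighbours in the
  analysed graph.
* local average connectivity (LAC) — mean, over a node's neighbours, of
  their degree within the subgraph induced by those neighbours.

All metrics of a degree-0 node are 0 by convention so that downstream median
thresholds are well defined. Computations run on a sorted-node copy of the
input so floating-point accumulation order, and hence output, is reproducible.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "neighborhood_connectivity",
    "local_average_connectivity",
    "compute_all",
    "METRICS",
]

METRICS = ("degree", "betweenness", "closeness", "neighborhood_connectivity", "lac")


def _sorted_copy(net: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges))
    return g


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    return {v: net.degree(v) for v in net.nodes}


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    g = _sorted_copy(net)
    return nx.betweenness_centrality(g, normalized=False)


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    g = _sorted_copy(net)
    # wf_improved=False gives the per-component (c-1)/sum(d) convention.
    return nx.closeness_centrality(g, wf_improved=False)


def neighborhood_connectivity(net: nx.Graph) -> dict[str, float]:
    out: dict[str, float] = {}
    for v in net.nodes:
        nbrs = sorted(net.neighbors(v))
        out[v] = sum(net.degree(u) for u in nbrs) / len(nbrs) if nbrs else 0.0
    return out


def local_average_connectivity(net: nx.Graph) -> dict[str, float]:
    out: dict[str, float] = {}
    for v in net.nodes:
        nbrs = set(net.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        # Degree sum within the neighbour-induced subgraph = 2 * its edge count.
        internal_edges = sum(
            1 for u in nbrs for w in net.neighbors(u) if w in nbrs and u < w
        )
        out[v] = 2.0 * internal_edges / len(nbrs)
    return out


def compute_all(net: nx.Graph) -> pd.DataFrame:
    """All five metrics, one row per node, lexicographic node order.

    Columns: degree, betweenness, closeness, neighborhood_connectivity, lac.
    """
    nodes = sorted(net.nodes)
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    clo = closeness_centrality(net)
    nc = neighborhood_connectivity(net)
    lac = local_average_connectivity(net)
    table = pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "neighborhood_connectivity": [nc[v] for v in nodes],
            "lac": [lac[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return table
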