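"""Readers and writers for the pipeline's plain-text formats.

Supported graph dialects:

``tsv``
    Two tab-separated identifier columns per edge. Extra columns (e.g. a
    weight) are ignored with a warning; graphs here are unweighted. Isolated
    nodes are listed one per line under a ``#nodes`` section header.
``sif``
    Cytoscape simple-interaction format, ``A pp B [C ...]``; a line with a
    single token declares an isolated node.
``graphml``
    Delegated to networkx.

Seed sets are one identifier per line (``#`` comments allowed); annotation
databases use GMT (term_id TAB description TAB member...).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import AnnotationDB
from .network import SeedSet

__all__ = [
    "ParseError",
    "read_edge_list",
    "write_network",
    "read_seed_set",
    "write_seed_set",
    "read_gmt",
    "write_gmt",
    "write_centrality_table",
    "read_centrality_table",
]

logger = logging.getLogger(__name__)

GRAPH_DIALECTS = ("tsv", "sif", "graphml")


class ParseError(ValueError):
    """A line of an input file does not parse under the declared dialect."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _check_dialect(dialect: str) -> None:
    if dialect not in GRAPH_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {GRAPH_DIALECTS}")


def read_edge_list(path: str | Path, dialect: str = "tsv") -> nx.Graph:
    """Read an undirected simple graph.

    Duplicate lines and reversed duplicates collapse to one edge; self-loops
    are dropped with a logged warning and counted in
    ``graph.graph["dropped_self_loops"]``. An empty file is an error.
    """
    _check_dialect(dialect)
    path = Path(path)
    if dialect == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        out.add_nodes_from(str(n) for n in g.nodes)
        dropped = 0
        for u, v in g.edges():
            if u == v:
                dropped += 1
                continue
            out.add_edge(str(u), str(v))
        if dropped:
            logger.warning("dropped %d self-loop(s) from %s", dropped, path)
        out.graph["dropped_self_loops"] = dropped
        if out.number_of_nodes() == 0:
            raise ParseError(path, 0, "graph file contains no nodes")
        return out

    out = nx.Graph()
    dropped = 0
    warned_extra = False
    node_section = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.strip().lower() in ("#nodes", "# nodes"):
                node_section = True
                continue
            if line.lstrip().startswith("#"):
                continue
            if dialect == "tsv":
                fields = line.split("\t")
                if node_section or len(fields) == 1:
                    tok = fields[0].strip()
                    if not tok or len(fields) > 1:
                        raise ParseError(path, lineno, f"malformed node line: {line!r}")
                    if node_section:
                        out.add_node(tok)
                        continue
                    raise ParseError(
                        path, lineno, "single-column line outside a #nodes section"
                    )
                if len(fields) > 2 and not warned_extra:
                    logger.warning(
                        "%s:%d: extra columns ignored (graphs are unweighted)",
                        path, lineno,
                    )
                    warned_extra = True
                u, v = fields[0].strip(), fields[1].strip()
                if not u or not v:
                    raise ParseError(path, lineno, f"empty identifier in: {line!r}")
                dropped += _add_edge(out, u, v)
            else:  # sif
                tokens = line.split()
                if len(tokens) == 1:
                    out.add_node(tokens[0])
                elif len(tokens) >= 3:
                    src = tokens[0]
                    for tgt in tokens[2:]:
                        dropped += _add_edge(out, src, tgt)
                else:
                    raise ParseError(
                        path, lineno,
                        f"SIF line needs 1 token or >= 3 tokens, got {len(tokens)}",
                    )
    if out.number_of_nodes() == 0:
        raise ParseError(path, 0, "graph file contains no nodes")
    if dropped:
        logger.warning("dropped %d self-loop(s) from %s", dropped, path)
    out.graph["dropped_self_loops"] = dropped
    return out


def _add_edge(g: nx.Graph, u: str, v: str) -> int:
    if u == v:
        g.add_node(u)
        return 1
    g.add_edge(u, v)
    return 0


def write_network(net: nx.Graph, path: str | Path, dialect: str = "tsv") -> None:
    """Write a graph so it re-reads identically; node order is lexicographic."""
    _check_dialect(dialect)
    path = Path(path)
    if dialect == "graphml":
        out = nx.Graph()
        out.add_nodes_from(sorted(net.nodes))
        out.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges))
        nx.write_graphml(out, path)
        return

    edges = sorted(tuple(sorted(e)) for e in net.edges)
    isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
    with open(path, "w") as fh:
        if dialect == "tsv":
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
            if isolated:
                fh.write("#nodes\n")
                for n in isolated:
                    fh.write(f"{n}\n")
        else:  # sif
            for u, v in edges:
                fh.write(f"{u} pp {v}\n")
            for n in isolated:
                fh.write(f"{n}\n")


def read_seed_set(path: str | Path, name: str | None = None) -> SeedSet:
    """Read a one-identifier-per-line seed list; name defaults to the file stem."""
    path = Path(path)
    members = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if any(c.isspace() for c in line):
                raise ParseError(path, lineno, f"identifier contains whitespace: {line!r}")
            members.append(line)
    if not members:
        raise ParseError(path, 0, "seed file contains no identifiers")
    return SeedSet(name=name or path.stem, members=frozenset(members))


def write_seed_set(seeds: SeedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(seeds.members):
            fh.write(f"{m}\n")


def read_gmt(path: str | Path, background: set[str] | None = None) -> AnnotationDB:
    """Read a GMT annotation database.

    The background defaults to the union of all term members; pass an
    explicit background (e.g. the interactome node set) to override.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    path, lineno, "GMT line needs term_id, description, >=1 member"
                )
            tid, desc = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise ParseError(path, lineno, f"term {tid} has no members")
            terms[tid] = (desc, members)
    if not terms:
        raise ParseError(path, 0, "GMT file contains no terms")
    if background is None:
        background = set()
        for _, members in terms.values():
            background |= members
    return AnnotationDB(terms=terms, background=frozenset(background))


def write_gmt(db: AnnotationDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(db.terms):
            desc, members = db.terms[tid]
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a centrality table as TSV with 10 significant digits."""
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_centrality_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node")
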