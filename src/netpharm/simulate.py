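"""Synthetic interactomes, seed sets, and annotation databases with planted truth.

The generator emulates the statistical structure the screening cascade
assumes: a hub-dominated (scale-free-like) interactome grown by preferential
attachment, a dense planted core module reachable from both the drug-side and
disease-side seed sets, and annotation terms over-represented in that core.
All randomness derives from a single integer seed; every output is a pure
function of the :class:`SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .network import SeedSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_interactome",
    "sample_seed_sets",
    "simulate_annotation_db",
    "simulate_study",
]


class ConfigurationError(ValueError):
    """A SimulationConfig field violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Attributes
    ----------
    n_proteins:
        Number of nodes in the interactome.
    attachment_edges:
        Edges added per new node during preferential-attachment growth
        (``m`` of the Barabási–Albert model).
    core_size:
        Number of nodes in the planted core module (0 disables planting).
    core_density:
        Target edge density of the subgraph induced by the core, reached by
        adding random core–core edges after growth.
    n_drug_seeds, n_disease_seeds:
        Sizes of the two seed-target sets.
    seed_core_fraction:
        Fraction of each seed set drawn from core nodes or their direct
        neighbours; the remainder is drawn from the rest of the interactome.
    n_terms:
        Number of annotation terms in the generated GMT database.
    term_size_range:
        Inclusive (min, max) bounds for term sizes, sampled uniformly.
    n_enriched_terms:
        Number of terms planted to be over-represented in the core.
    enrichment_strength:
        Fraction of each enriched term's members drawn from the core.
    rng_seed:
        Single integer seed; identical seeds give bit-identical outputs.
    """

    n_proteins: int = 500
    attachment_edges: int = 3
    core_size: int = 30
    core_density: float = 0.8
    n_drug_seeds: int = 40
    n_disease_seeds: int = 40
    seed_core_fraction: float = 0.8
    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 30)
    n_enriched_terms: int = 5
    enrichment_strength: float = 0.9
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 2:
            raise ConfigurationError("n_proteins must be >= 2")
        if not 1 <= self.attachment_edges < self.n_proteins:
            raise ConfigurationError(
                "attachment_edges must satisfy 1 <= attachment_edges < n_proteins"
            )
        if not 0 <= self.core_size < self.n_proteins:
            raise ConfigurationError("core_size must satisfy 0 <= core_size < n_proteins")
        if not 0.0 <= self.core_density <= 1.0:
            raise ConfigurationError("core_density must lie in [0, 1]")
        if self.n_drug_seeds < 1 or self.n_disease_seeds < 1:
            raise ConfigurationError("seed set sizes must be >= 1")
        if self.n_drug_seeds + self.n_disease_seeds > self.n_proteins:
            raise ConfigurationError(
                "n_drug_seeds + n_disease_seeds must not exceed n_proteins"
            )
        if not 0.0 <= self.seed_core_fraction <= 1.0:
            raise ConfigurationError("seed_core_fraction must lie in [0, 1]")
        if self.n_terms < 0 or self.n_enriched_terms < 0:
            raise ConfigurationError("term counts must be >= 0")
        if self.n_enriched_terms > self.n_terms:
            raise ConfigurationError("n_enriched_terms must not exceed n_terms")
        lo, hi = self.term_size_range
        if not (2 <= lo <= hi):
            raise ConfigurationError("term_size_range min must be >= 2 and <= max")
        if hi > self.n_proteins:
            raise ConfigurationError("term_size_range max must not exceed n_proteins")
        if not 0.0 <= self.enrichment_strength <= 1.0:
            raise ConfigurationError("enrichment_strength must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["term_size_range"] = list(self.term_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "term_size_range" in d:
            d["term_size_range"] = tuple(d["term_size_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure of a simulated study, used to score recovery."""

    core_nodes: frozenset[str] = field(default_factory=frozenset)
    enriched_term_ids: frozenset[str] = field(default_factory=frozenset)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "core_nodes": sorted(self.core_nodes),
            "enriched_term_ids": sorted(self.enriched_term_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            core_nodes=frozenset(payload["core_nodes"]),
            enriched_term_ids=frozenset(payload["enriched_term_ids"]),
        )


# Fixed spawn keys give each operation its own stream derived from rng_seed,
# so outputs do not depend on the order the operations are invoked in.
_STREAM_INTERACTOME = 0
_STREAM_SEEDS = 1
_STREAM_ANNOTATION = 2


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(stream,))
    )


def _node_id(i: int, n: int) -> str:
    width = max(4, len(str(n)))
    return f"P{i:0{width}d}"


def _term_id(i: int, n: int) -> str:
    width = max(4, len(str(n)))
    return f"T{i:0{width}d}"


def simulate_interactome(config: SimulationConfig) -> tuple[nx.Graph, GroundTruth]:
    """Grow a preferential-attachment interactome and densify a planted core.

    Returns a connected simple undirected graph with nodes ``P0001..Pnnnn``
    plus a :class:`GroundTruth` naming the core nodes (``enriched_term_ids``
    is filled later by :func:`simulate_annotation_db`).
    """
    config.validate()
    rng = _rng(config, _STREAM_INTERACTOME)

    raw = nx.barabasi_albert_graph(config.n_proteins, config.attachment_edges, seed=rng)
    mapping = {i: _node_id(i + 1, config.n_proteins) for i in raw.nodes}
    graph = nx.relabel_nodes(raw, mapping)
    graph.graph["provenance"] = "interactome"

    nodes_sorted = sorted(graph.nodes)
    core: list[str] = []
    if config.core_size > 0:
        core = sorted(
            rng.choice(nodes_sorted, size=config.core_size, replace=False).tolist()
        )
        _densify(graph, core, config.core_density, rng)

    truth = GroundTruth(core_nodes=frozenset(core))
    return graph, truth


def _densify(graph: nx.Graph, core: list[str], density: float, rng: np.random.Generator) -> None:
    """Add random missing core-core edges until the induced density >= target."""
    s = len(core)
    if s < 2:
        return
    possible = s * (s - 1) // 2
    target_edges = math.ceil(density * possible)
    missing = [
        (core[i], core[j])
        for i in range(s)
        for j in range(i + 1, s)
        if not graph.has_edge(core[i], core[j])
    ]
    have = possible - len(missing)
    deficit = target_edges - have
    if deficit <= 0:
        return
    picks = rng.choice(len(missing), size=deficit, replace=False)
    for idx in sorted(picks.tolist()):
        graph.add_edge(*missing[idx])


def sample_seed_sets(
    interactome: nx.Graph, truth: GroundTruth, config: SimulationConfig
) -> tuple[SeedSet, SeedSet]:
    """Draw the drug-side and disease-side seed-target sets.

    Each set contains ``ceil(seed_core_fraction * size)`` members sampled
    uniformly from the core-adjacent pool (core nodes plus their direct
    neighbours) and the remainder sampled uniformly from the rest of the
    interactome. The two sets are drawn independently and may overlap.
    """
    config.validate()
    rng = _rng(config, _STREAM_SEEDS)

    core = set(truth.core_nodes)
    adjacent = set(core)
    for c in truth.core_nodes:
        adjacent.update(interactome.neighbors(c))
    pool_core = sorted(adjacent)
    pool_rest = sorted(set(interactome.nodes) - adjacent)

    def draw(size: int, name: str) -> SeedSet:
        n_core = math.ceil(config.seed_core_fraction * size)
        n_rest = size - n_core
        if n_core > len(pool_core):
            raise ValueError(
                f"cannot draw {n_core} core-adjacent seeds: pool has {len(pool_core)}"
            )
        if n_rest > len(pool_rest):
            raise ValueError(
                f"cannot draw {n_rest} non-core seeds: pool has {len(pool_rest)}"
            )
        members: list[str] = []
        if n_core:
            members += rng.choice(pool_core, size=n_core, replace=False).tolist()
        if n_rest:
            members += rng.choice(pool_rest, size=n_rest, replace=False).tolist()
        return SeedSet(name=name, members=frozenset(members))

    return draw(config.n_drug_seeds, "drug"), draw(config.n_disease_seeds, "disease")


def simulate_annotation_db(
    interactome: nx.Graph, truth: GroundTruth, config: SimulationConfig
):
    """Generate an annotation-term database with terms planted in the core.

    The first ``n_enriched_terms`` terms draw at least
    ``enrichment_strength`` of their members from the core; the rest draw
    uniformly from all nodes. The background is the full node set. Updates
    ``truth.enriched_term_ids`` in place and returns the database.
    """
    from .enrichment import AnnotationDB

    config.validate()
    rng = _rng(config, _STREAM_ANNOTATION)

    nodes = sorted(interactome.nodes)
    core = sorted(truth.core_nodes)
    non_core = sorted(set(nodes) - set(core))
    lo, hi = config.term_size_range

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    enriched_ids: list[str] = []
    for i in range(1, config.n_terms + 1):
        tid = _term_id(i, config.n_terms)
        size = int(rng.integers(lo, hi + 1))
        if i <= config.n_enriched_terms:
            n_core_members = math.ceil(config.enrichment_strength * size)
            if n_core_members > len(core):
                raise ConfigurationError(
                    f"enriched term of size {size} needs {n_core_members} core members "
                    f"but the core has only {len(core)}"
                )
            n_rest = size - n_core_members
            if n_rest > len(non_core):
                raise ConfigurationError("not enough non-core nodes for term members")
            members = rng.choice(core, size=n_core_members, replace=False).tolist()
            if n_rest:
                members += rng.choice(non_core, size=n_rest, replace=False).tolist()
            desc = f"planted core module term {i}"
            enriched_ids.append(tid)
        else:
            members = rng.choice(nodes, size=size, replace=False).tolist()
            desc = f"background term {i}"
        terms[tid] = (desc, frozenset(members))

    truth.enriched_term_ids = frozenset(enriched_ids)
    return AnnotationDB(terms=terms, background=frozenset(nodes))


def simulate_study(config: SimulationConfig):
    """Run all three generators; returns (interactome, drug, disease, db, truth)."""
    interactome, truth = simulate_interactome(config)
    drug, disease = sample_seed_sets(interactome, truth, config)
    db = simulate_annotation_db(interactome, truth, config)
    return interactome, drug, disease, db, truth
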