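"""End-to-end orchestration: simulate/load, build, intersect, screen, enrich, assemble.

One YAML (or JSON) config drives a full run. Exactly one of the ``simulate``
or ``inputs`` sections must be present:

.. code-block:: yaml

    simulate:            # synthetic study; any SimulationConfig field
      n_proteins: 500
      rng_seed: 7
    # inputs:            # or real files
    #   interactome: interactome.tsv
    #   interactome_dialect: tsv
    #   drug_seeds: drug.txt
    #   disease_seeds: disease.txt
    #   gmt: terms.gmt
    screening:
      median_scope: stage
    enrichment:
      alpha: 0.05
    ctpd:
      compound: compound
      disease: disease

Every intermediate artifact is written into the output directory; a JSON
run report (stage counts, thresholds, core targets, significant terms,
config echo, version, seed) is written last. Counts in the report always
equal recounts from the emitted stage files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ctpd import build_ctpd, export_ctpd
from .enrichment import enrich, results_to_frame
from .io import read_edge_list, read_gmt, read_seed_set, write_gmt, write_network, write_seed_set
from .network import build_seed_network
from .screening import run_screening, save_screening_result, top_k_by_degree
from .simulate import SimulationConfig, simulate_study

__all__ = ["RunReport", "run_all", "load_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline config is missing or misusing a field."""


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    stage_counts: dict = field(default_factory=dict)
    hit_hub_degree_threshold: float = 0.0
    core_thresholds: dict = field(default_factory=dict)
    median_scope: str = "stage"
    core_targets: list = field(default_factory=list)
    top_targets_by_degree: list = field(default_factory=list)
    significant_terms: list = field(default_factory=list)
    n_terms_tested: int = 0
    config: dict = field(default_factory=dict)
    version: str = __version__
    rng_seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def run_all(config: str | Path | dict, outdir: str | Path) -> RunReport:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ConfigError("config needs exactly one of the sections 'simulate' or 'inputs'")

    rng_seed = None
    truth = None
    if has_sim:
        sim_cfg = SimulationConfig.from_dict(cfg["simulate"] or {})
        rng_seed = sim_cfg.rng_seed
        logger.info("[simulate] generating synthetic study (seed %d)", rng_seed)
        interactome, drug_seeds, disease_seeds, db, truth = simulate_study(sim_cfg)
        write_network(interactome, outdir / "interactome.tsv", dialect="tsv")
        write_network(interactome, outdir / "interactome.sif", dialect="sif")
        write_seed_set(drug_seeds, outdir / "drug_seeds.txt")
        write_seed_set(disease_seeds, outdir / "disease_seeds.txt")
        write_gmt(db, outdir / "annotation.gmt")
        truth.to_json(outdir / "ground_truth.json")
    else:
        inputs = cfg["inputs"] or {}
        for key in ("interactome", "drug_seeds", "disease_seeds", "gmt"):
            if key not in inputs:
                raise ConfigError(f"inputs section is missing the field '{key}'")
        dialect = inputs.get("interactome_dialect", "tsv")
        logger.info("[inputs] reading interactome from %s", inputs["interactome"])
        interactome = read_edge_list(inputs["interactome"], dialect=dialect)
        drug_seeds = read_seed_set(inputs["drug_seeds"], name="drug")
        disease_seeds = read_seed_set(inputs["disease_seeds"], name="disease")
        db = read_gmt(inputs["gmt"], background=set(interactome.nodes))

    logger.info("[build] expanding seed sets one hop")
    drug_net = build_seed_network(interactome, drug_seeds)
    disease_net = build_seed_network(interactome, disease_seeds)
    write_network(drug_net, outdir / "drug_network.tsv")
    write_network(disease_net, outdir / "disease_network.tsv")

    scr_cfg = cfg.get("screening") or {}
    median_scope = scr_cfg.get("median_scope", "stage")
    logger.info("[screen] running two-stage median cascade (scope=%s)", median_scope)
    screening = run_screening(drug_net, disease_net, median_scope=median_scope)
    save_screening_result(screening, outdir / "screening")

    enr_cfg = cfg.get("enrichment") or {}
    alpha = float(enr_cfg.get("alpha", 0.05))
    core_targets = sorted(screening.core.nodes)
    results = []
    if core_targets:
        logger.info("[enrich] testing %d terms against %d core targets",
                    len(db.terms), len(core_targets))
        results = enrich(
            core_targets, db, alpha=alpha,
            test_zero_overlap=bool(enr_cfg.get("test_zero_overlap", False)),
        )
        results_to_frame(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    else:
        logger.warning("[enrich] skipped: screening produced no core targets")

    ctpd_cfg = cfg.get("ctpd") or {}
    compound = str(ctpd_cfg.get("compound", "compound"))
    disease = str(ctpd_cfg.get("disease", "disease"))
    if core_targets:
        logger.info("[ctpd] assembling %s-target-pathway-%s network", compound, disease)
        ctpd_net = build_ctpd(compound, core_targets, results, disease, db)
        export_ctpd(ctpd_net, outdir / "ctpd.graphml", dialect="graphml")
        export_ctpd(ctpd_net, outdir / "ctpd.tsv", dialect="tsv")

    n_top = min(15, len(core_targets)) if core_targets else 0
    report = RunReport(
        stage_counts=screening.stage_counts(),
        hit_hub_degree_threshold=screening.hit_hub_threshold,
        core_thresholds=screening.core_thresholds.as_dict(),
        median_scope=median_scope,
        core_targets=core_targets,
        top_targets_by_degree=[
            list(t) for t in top_k_by_degree(screening.tables["core"], n_top)
        ] if n_top else [],
        significant_terms=sorted(r.term_id for r in results if r.significant),
        n_terms_tested=len(results),
        config=_jsonable(cfg),
        rng_seed=rng_seed,
    )
    report.to_json(outdir / "report.json")
    logger.info("[done] report written to %s", outdir / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
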