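"""End-to-end orchestration: ADMET → target sets → ORA → networks → docking.

A single config (YAML/JSON file or dict) names either synthetic generator
parameters or real input files for each stage.  The pipeline executes the
stages in order, writes every intermediate artifact to the output
directory, and returns a RunSummary with the counts at each stage, the
config hash and the seed.  Any stage failure aborts with the stage name
and cause; artifacts written before the failure are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import netanalysis
from .admet_screen import DL_MIN_DEFAULT, OB_MIN_DEFAULT, screen_compounds
from .docking_summary import energy_matrix, grade_energies, rank_pairs
from .enrichment import run_ora
from .io_model import (
    GeneSet,
    read_compound_table,
    read_docking_table,
    read_edge_list,
    read_gene_list,
    read_gmt,
    read_target_map,
    write_compound_table,
    write_edge_list,
    write_gene_list,
    write_results,
    write_target_map,
)
from .synthetic_data import SynthConfig, write_all
from .target_sets import intersect_drug_disease, union_sources, venn_regions

logger = logging.getLogger("netpharm")

__all__ = ["RunSummary", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunSummary:
    """Machine-readable account of one pipeline run."""

    seed: int | None
    config_hash: str
    counts: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def load_config(path: str | Path) -> dict:
    """Parse a YAML or JSON pipeline config file."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage guard: re-raise with stage context."""
    class _Guard:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info(
                "stage %s: done in %.2fs", name, time.perf_counter() - self.t0
            )
            return False

    return _Guard()


def run_pipeline(config: dict | str | Path | SynthConfig, outdir: str | Path) -> RunSummary:
    """Run the full screening chain and write all artifacts under ``outdir``.

    ``config`` is a dict (or YAML/JSON path) with either a ``synthetic``
    block (SynthConfig fields — inputs are generated first) or an
    ``inputs`` block naming files: ``compounds``, ``disease_sources`` (list
    of gene-list paths), ``drug_targets`` (TSV pairs), ``annotation_gmt``,
    and either ``ppi_edges`` (edge list) or ``hub_degrees`` (a published
    per-node degree table from which the hub subnetwork is reconstructed),
    plus optional ``docking`` (ligand/receptor/energy TSV).  A ``params``
    block overrides stage parameters (admet.ob_min, admet.dl_min,
    ora.q_max, screen.rounds, docking.top_n).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    if isinstance(config, SynthConfig):
        config = {"synthetic": asdict(config)}

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_file = logging.FileHandler(outdir / "pipeline.log")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_file)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(log_file)
        log_file.close()


def _run(config: dict, outdir: Path) -> RunSummary:
    params = config.get("params", {})
    seed = None

    if "synthetic" in config:
        synth_cfg = SynthConfig(**config["synthetic"])
        seed = synth_cfg.seed
        with _stage("synthetic_data"):
            write_all(synth_cfg, outdir / "inputs")
        inputs = {
            "compounds": outdir / "inputs" / "compounds.tsv",
            "disease_sources": sorted(
                str(p) for p in (outdir / "inputs").glob("disease_*.txt")
            ),
            "drug_targets": outdir / "inputs" / "drug_targets.tsv",
            "annotation_gmt": outdir / "inputs" / "annotation.gmt",
            "ppi_edges": outdir / "inputs" / "ppi_edges.tsv",
            "docking": outdir / "inputs" / "docking.tsv",
        }
    elif "inputs" in config:
        inputs = config["inputs"]
    else:
        raise PipelineError("config needs a 'synthetic' or 'inputs' block")

    summary = RunSummary(seed=seed, config_hash=_config_hash(config))
    counts = summary.counts

    # --- stage 1: ADMET screen -------------------------------------------
    with _stage("admet"):
        compounds = read_compound_table(inputs["compounds"])
        admet = params.get("admet", {})
        kept = screen_compounds(
            compounds,
            ob_min=admet.get("ob_min", OB_MIN_DEFAULT),
            dl_min=admet.get("dl_min", DL_MIN_DEFAULT),
        )
        counts["compounds_total"] = len(compounds)
        counts["compounds_kept"] = len(kept)
        write_compound_table(kept, outdir / "compounds_kept.tsv")
        summary.artifacts["compounds_kept"] = "compounds_kept.tsv"

    # --- stage 2: disease union and drug-disease intersection ------------
    with _stage("target_sets"):
        sources = [
            read_gene_list(p, name=f"S{i}")
            for i, p in enumerate(inputs.get("disease_sources", []), start=1)
        ]
        disease = union_sources(sources, name="disease_union")
        counts["disease_sources"] = len(sources)
        counts["disease_union"] = len(disease)
        if len(sources) >= 2:
            write_results(venn_regions(sources), outdir / "venn_regions.json")
            summary.artifacts["venn_regions"] = "venn_regions.json"
        write_gene_list(disease, outdir / "disease_union.txt")

        target_map = read_target_map(inputs["drug_targets"])
        kept_names = {c.name for c in kept} | {c.mol_id for c in kept}
        target_map = {
            name: gs for name, gs in target_map.items() if name in kept_names
        }
        counts["drug_target_genes"] = len(
            set().union(*(gs.genes for gs in target_map.values()))
            if target_map else set()
        )
        intersection, per_compound = intersect_drug_disease(target_map, disease)
        counts["intersection"] = len(intersection)
        write_gene_list(intersection, outdir / "intersection.txt")
        summary.artifacts["intersection"] = "intersection.txt"

    if counts["intersection"] == 0:
        logger.warning(
            "drug-disease intersection is empty; downstream stages skipped"
        )
        summary.skipped = ["enrichment", "bipartite", "hub_screen", "docking"]
        _write_summary(summary, outdir)
        return summary

    # --- stage 3: over-representation analysis ---------------------------
    if inputs.get("annotation_gmt"):
        with _stage("enrichment"):
            terms = read_gmt(inputs["annotation_gmt"])
            ora = params.get("ora", {})
            rows = run_ora(intersection, terms, q_max=ora.get("q_max", 0.05))
            counts["terms_tested"] = len(rows)
            counts["terms_significant"] = sum(r.significant for r in rows)
            write_results(rows, outdir / "enrichment.csv")
            summary.artifacts["enrichment"] = "enrichment.csv"
    else:
        summary.skipped.append("enrichment")

    # --- stage 4: bipartite component-target network ----------------------
    with _stage("bipartite"):
        nonempty = {c: gs for c, gs in per_compound.items() if gs.genes}
        bipartite = netanalysis.build_bipartite(nonempty)
        counts["bipartite_nodes"] = bipartite.number_of_nodes()
        counts["bipartite_edges"] = bipartite.number_of_edges()
        compound_degrees = sorted(
            ((c, bipartite.degree(c)) for c in nonempty),
            key=lambda kv: (-kv[1], kv[0]),
        )
        if compound_degrees:
            counts["top_compound"] = compound_degrees[0][0]
            counts["top_compound_degree"] = compound_degrees[0][1]
        write_edge_list(bipartite, outdir / "component_target_edges.tsv")
        summary.artifacts["component_target"] = "component_target_edges.tsv"

    # --- stage 5: PPI centralities and median hub screen ------------------
    with _stage("hub_screen"):
        rounds = params.get("screen", {}).get("rounds", 2)
        if inputs.get("ppi_edges"):
            ppi = read_edge_list(inputs["ppi_edges"])
            counts["ppi_nodes"] = ppi.number_of_nodes()
            counts["ppi_edges"] = ppi.number_of_edges()
            screen = netanalysis.median_screen(ppi, rounds=rounds)
            for rnd in screen:
                counts[f"survivors_round{rnd.round_index}"] = len(rnd.survivors)
                write_results(
                    netanalysis.centrality_table(rnd.subgraph),
                    outdir / f"centralities_round{rnd.round_index}.csv",
                )
            hub_graph = screen[-1].subgraph
            write_results(
                {
                    f"round{r.round_index}": r.thresholds for r in screen
                },
                outdir / "screen_thresholds.json",
            )
        elif inputs.get("hub_degrees"):
            # published degree column instead of an edge list: reconstruct
            # a realization of the hub subnetwork from the degree sequence
            degrees = {
                gene: int(row["degree"])
                for gene, row in _read_degree_table(inputs["hub_degrees"]).items()
            }
            hub_graph = netanalysis.graph_from_degree_sequence(degrees)
            write_results(
                netanalysis.centrality_table(hub_graph),
                outdir / "hub_centralities.csv",
            )
        else:
            raise ValueError("config must provide ppi_edges or hub_degrees")
        counts["hub_subnetwork_nodes"] = hub_graph.number_of_nodes()
        counts["hub_subnetwork_edges"] = hub_graph.number_of_edges()
        write_edge_list(hub_graph, outdir / "hub_subnetwork_edges.tsv")
        summary.artifacts["hub_subnetwork"] = "hub_subnetwork_edges.tsv"

    # --- stage 6: docking summary -----------------------------------------
    if inputs.get("docking"):
        with _stage("docking"):
            records = grade_energies(read_docking_table(inputs["docking"]))
            top_n = params.get("docking", {}).get("top_n", 10)
            top = rank_pairs(records, top_n=top_n)
            for grade in ("strong", "good", "weak"):
                counts[f"docking_{grade}"] = sum(
                    r.grade == grade for r in records
                )
            write_results(records, outdir / "docking_graded.csv")
            write_results(top, outdir / "docking_top.csv")
            energy_matrix(records).to_csv(outdir / "docking_matrix.csv")
            summary.artifacts["docking"] = "docking_graded.csv"
    else:
        summary.skipped.append("docking")

    _write_summary(summary, outdir)
    return summary


def _read_degree_table(path) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        keys = [h.strip().lower() for h in header[1:]]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0]:
                out[fields[0]] = dict(zip(keys, (float(x) for x in fields[1:])))
    return out


def _write_summary(summary: RunSummary, outdir: Path) -> None:
    (outdir / "run_summary.json").write_text(summary.to_json() + "\n")
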