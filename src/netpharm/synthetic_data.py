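"""Synthetic inputs with the statistical structure the pipeline assumes.

Every upstream data source the screening chain consumes is emulated here so
the full pipeline can run and be tested without any database access:

* a compound property table whose OB/DL values straddle the ADMET cutoffs,
  parameterized by the target pass fraction of the joint filter;
* four partially overlapping disease-gene sources (shared-core sampling
  controls the pairwise overlap);
* a compound-to-target map whose targets partially fall inside the disease
  union, so the drug-disease intersection is non-empty by construction;
* annotation term sets with a handful of planted enriched terms that
  oversample a signal gene set;
* a PPI graph with an Erdős–Rényi backbone plus planted high-degree hubs;
* a uniform ligand x receptor binding-energy matrix.

One integer seed drives a named sub-stream per generator, so adding a new
generator never perturbs the outputs of existing ones; a fixed config is
byte-identical across runs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.stats import norm

from .io_model import (
    Compound,
    DockingRecord,
    GeneSet,
    grade_energy,
    write_compound_table,
    write_edge_list,
    write_gene_list,
    write_gmt,
    write_target_map,
)

__all__ = [
    "SynthConfig",
    "gen_compounds",
    "gen_disease_sources",
    "gen_drug_targets",
    "gen_annotation",
    "gen_ppi",
    "gen_docking_matrix",
    "write_all",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study conditions.

    Defaults mirror the screening scenario the pipeline targets: a
    compound table with about half the candidates passing the ADMET filter,
    four disease sources of decreasing size (a large aggregator plus three
    curated lists), a ~3000-gene desk-scale universe, a 117-node PPI screen
    with 11 planted hubs, and annotation sets with 5 planted enriched terms.
    When ``ob_mean``/``dl_mean`` are left unset they are derived from
    ``frac_pass`` so that the expected joint pass fraction of the OB/DL
    filter matches it (the per-axis pass probability is sqrt(frac_pass)).
    """

    seed: int = 0
    # compound table
    n_compounds: int = 200
    ob_mean: float | None = None   # percent; derived from frac_pass if None
    ob_sd: float = 15.0
    dl_mean: float | None = None   # derived from frac_pass if None
    dl_sd: float = 0.15
    frac_pass: float = 0.5
    # gene universe and disease sources
    n_universe: int = 3000
    n_sources: int = 4
    source_sizes: tuple[int, ...] = (800, 300, 150, 100)
    pairwise_overlap: float = 0.2
    # drug targets
    targets_per_compound: tuple[int, int] = (5, 40)
    disease_target_frac: float = 0.3
    # annotation
    n_terms: int = 200
    n_enriched_terms: int = 5
    enrichment_strength: float = 8.0
    term_size_range: tuple[int, int] = (20, 200)
    # PPI
    ppi_nodes: int = 117
    ppi_edge_prob: float = 0.05
    n_hubs: int = 11
    hub_degree_boost: int = 20

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        for name in ("n_compounds", "n_universe", "n_terms", "ppi_nodes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("frac_pass", "pairwise_overlap", "ppi_edge_prob",
                     "disease_target_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.source_sizes) != self.n_sources:
            raise ValueError("source_sizes length must equal n_sources")
        if self.enrichment_strength <= 1.0:
            raise ValueError("enrichment_strength must exceed 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named sub-stream of the config seed."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


def _universe_genes(cfg: SynthConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(1, cfg.n_universe + 1)]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_compounds(cfg: SynthConfig) -> list[Compound]:
    """Compound table with OB/DL drawn from clamped normals.

    OB ~ Normal(ob_mean, ob_sd) clamped at 0; DL ~ Normal(dl_mean, dl_sd)
    clamped to [0, 1].  With derived means the expected fraction passing
    the joint (OB >= 30, DL >= 0.18) filter equals ``frac_pass`` — the
    clamps only move values that fail the filter anyway.
    """
    rng = cfg.rng("compounds")
    p_axis = float(np.sqrt(cfg.frac_pass))
    z = float(norm.ppf(p_axis)) if 0.0 < p_axis < 1.0 else 0.0
    ob_mean = cfg.ob_mean if cfg.ob_mean is not None else 30.0 + cfg.ob_sd * z
    dl_mean = cfg.dl_mean if cfg.dl_mean is not None else 0.18 + cfg.dl_sd * z
    ob = np.clip(rng.normal(ob_mean, cfg.ob_sd, cfg.n_compounds), 0.0, None)
    dl = np.clip(rng.normal(dl_mean, cfg.dl_sd, cfg.n_compounds), 0.0, 1.0)
    return [
        Compound(
            mol_id=f"SYN{i:04d}",
            name=f"compound-{i}",
            ob=round(float(ob[i - 1]), 2),
            dl=round(float(dl[i - 1]), 3),
        )
        for i in range(1, cfg.n_compounds + 1)
    ]


def gen_disease_sources(cfg: SynthConfig) -> list[GeneSet]:
    """Partially overlapping disease-gene sources via shared-core sampling.

    All sources contain a common core of size ≈ pairwise_overlap x mean
    source size; the remainder of each source is drawn independently from
    the rest of the universe, which makes the realized pairwise overlap
    (relative to the source sizes) track the requested level.
    """
    rng = cfg.rng("disease_sources")
    universe = np.array(_universe_genes(cfg))
    core_size = int(round(cfg.pairwise_overlap * float(np.mean(cfg.source_sizes))))
    core_size = min(core_size, min(cfg.source_sizes), cfg.n_universe)
    core_idx = rng.choice(len(universe), size=core_size, replace=False)
    core = set(universe[core_idx])
    rest = np.array(sorted(set(universe) - core))
    sources = []
    for i, size in enumerate(cfg.source_sizes, start=1):
        extra = rng.choice(len(rest), size=size - core_size, replace=False)
        genes = core | set(rest[extra])
        sources.append(GeneSet.from_iterable(f"S{i}", genes))
    return sources


def gen_drug_targets(
    cfg: SynthConfig,
    compounds: list[Compound],
    disease_union: GeneSet,
) -> dict[str, GeneSet]:
    """Per-compound target sets with a controlled disease-gene fraction.

    Each compound receives uniform(targets_per_compound) targets;
    ``disease_target_frac`` of them come from the disease union (so the
    drug-disease intersection is non-empty by construction), the rest from
    the remainder of the universe.
    """
    rng = cfg.rng("drug_targets")
    disease = np.array(sorted(disease_union.genes))
    background = np.array(
        sorted(set(_universe_genes(cfg)) - set(disease_union.genes))
    )
    lo, hi = cfg.targets_per_compound
    out: dict[str, GeneSet] = {}
    for compound in compounds:
        size = int(rng.integers(lo, hi + 1))
        n_disease = min(int(round(cfg.disease_target_frac * size)), len(disease))
        n_background = min(size - n_disease, len(background))
        picked: set[str] = set()
        if n_disease:
            picked |= set(disease[rng.choice(len(disease), n_disease, replace=False)])
        if n_background:
            picked |= set(
                background[rng.choice(len(background), n_background, replace=False)]
            )
        out[compound.name] = GeneSet.from_iterable(compound.name, picked)
    return out


def gen_annotation(
    cfg: SynthConfig,
    universe: GeneSet | None = None,
    signal_genes: GeneSet | None = None,
) -> list[GeneSet]:
    """Annotation term sets; the first ``n_enriched_terms`` are planted.

    Planted terms (named ``planted01`` ...) draw their members with the
    signal genes weighted ``enrichment_strength``-fold over background, so
    a query equal to the signal set recovers them at low q.  Background
    terms (``bg001`` ...) are uniform draws.
    """
    rng = cfg.rng("annotation")
    genes = (
        np.array(sorted(universe.genes))
        if universe is not None
        else np.array(_universe_genes(cfg))
    )
    signal = signal_genes.genes if signal_genes is not None else frozenset()
    weights = np.where(
        np.isin(genes, sorted(signal)), cfg.enrichment_strength, 1.0
    )
    weights = weights / weights.sum()
    lo, hi = cfg.term_size_range
    terms: list[GeneSet] = []
    for i in range(1, cfg.n_terms + 1):
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        if i <= cfg.n_enriched_terms and signal:
            idx = rng.choice(len(genes), size=size, replace=False, p=weights)
            name = f"planted{i:02d}"
        else:
            idx = rng.choice(len(genes), size=size, replace=False)
            name = f"bg{i:03d}"
        terms.append(GeneSet.from_iterable(name, genes[idx]))
    return terms


def gen_ppi(
    cfg: SynthConfig,
    nodes: GeneSet | None = None,
) -> tuple[nx.Graph, set[str]]:
    """Erdős–Rényi PPI backbone with planted high-degree hubs.

    Every node pair is an edge with probability ``ppi_edge_prob``; then
    ``n_hubs`` randomly chosen nodes are each wired to ``hub_degree_boost``
    additional random non-neighbors.  Returns the graph and the planted hub
    ids for recovery tests.
    """
    rng = cfg.rng("ppi")
    if nodes is not None:
        node_list = sorted(nodes.genes)
    else:
        node_list = [f"G{i:05d}" for i in range(1, cfg.ppi_nodes + 1)]
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(node_list)
    pairs = list(combinations(node_list, 2))
    mask = rng.random(len(pairs)) < cfg.ppi_edge_prob
    g.add_edges_from(p for p, keep in zip(pairs, mask) if keep)

    n_hubs = min(cfg.n_hubs, len(node_list))
    hub_idx = rng.choice(len(node_list), size=n_hubs, replace=False)
    hubs = {node_list[i] for i in sorted(hub_idx)}
    for hub in sorted(hubs):
        candidates = sorted(set(node_list) - set(g.neighbors(hub)) - {hub})
        boost = min(cfg.hub_degree_boost, len(candidates))
        if boost:
            chosen = rng.choice(len(candidates), size=boost, replace=False)
            g.add_edges_from((hub, candidates[i]) for i in sorted(chosen))
    return g, hubs


def gen_docking_matrix(
    cfg: SynthConfig,
    ligands: list[str],
    receptors: list[str],
) -> list[DockingRecord]:
    """Full ligand x receptor energy matrix, uniform in [-10.5, -4.0] kcal/mol."""
    rng = cfg.rng("docking")
    records = []
    for ligand in ligands:
        for receptor in receptors:
            energy = round(float(rng.uniform(-10.5, -4.0)), 1)
            records.append(
                DockingRecord(ligand, receptor, energy, grade_energy(energy))
            )
    return records


# ---------------------------------------------------------------------------
# One-shot fixture writer
# ---------------------------------------------------------------------------

def write_all(cfg: SynthConfig, outdir: str | Path) -> dict:
    """Generate the full input suite and write it in the pipeline's formats.

    Produces compounds.tsv, one gene list per disease source,
    drug_targets.tsv, annotation.gmt, ppi_edges.tsv, docking.tsv, and a
    ground_truth.json recording the planted hubs and enriched terms.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    compounds = gen_compounds(cfg)
    write_compound_table(compounds, outdir / "compounds.tsv")

    sources = gen_disease_sources(cfg)
    source_paths = []
    for src in sources:
        path = outdir / f"disease_{src.name}.txt"
        write_gene_list(src, path)
        source_paths.append(str(path))

    union = GeneSet(
        "disease_union", frozenset().union(*(s.genes for s in sources))
    )
    targets = gen_drug_targets(cfg, compounds, union)
    write_target_map(targets, outdir / "drug_targets.tsv")

    signal = GeneSet(
        "signal",
        frozenset().union(*(t.genes for t in targets.values())) & union.genes,
    )
    terms = gen_annotation(cfg, signal_genes=signal)
    write_gmt(terms, outdir / "annotation.gmt")

    ppi_nodes = GeneSet.from_iterable(
        "ppi_nodes", sorted(signal.genes)[: cfg.ppi_nodes]
    )
    graph, hubs = gen_ppi(cfg, ppi_nodes if len(ppi_nodes) else None)
    write_edge_list(graph, outdir / "ppi_edges.tsv")

    ligands = [c.name for c in compounds[: min(5, len(compounds))]]
    receptors = sorted(hubs)
    docking = gen_docking_matrix(cfg, ligands, receptors)
    with open(outdir / "docking.tsv", "w") as fh:
        fh.write("ligand\treceptor\tenergy\n")
        for r in docking:
            fh.write(f"{r.ligand}\t{r.receptor}\t{r.energy}\n")

    truth = {
        "planted_hubs": sorted(hubs),
        "planted_terms": [t.name for t in terms if t.name.startswith("planted")],
        "config": asdict(cfg),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
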