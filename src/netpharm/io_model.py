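"""Domain types and file formats shared by every pipeline stage.

The pipeline moves five kinds of objects between stages: compound records
(ADMET properties), named gene sets, undirected simple graphs, per-node
centrality records, and docking-energy records.  This module defines those
types and reads/writes every external text format the pipeline touches:
TSV/CSV compound tables, plain gene lists, GMT annotation files, SIF or
two-column edge lists, and CSV/JSON result exports.

Gene symbols are normalized by uppercasing and trimming whitespace only;
no alias resolution is attempted, so inputs are expected to carry
already-standardized symbols.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("netpharm")

__all__ = [
    "Compound",
    "GeneSet",
    "CentralityRecord",
    "EnrichmentRow",
    "DockingRecord",
    "FormatError",
    "normalize_symbol",
    "read_compound_table",
    "write_compound_table",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_target_map",
    "write_target_map",
    "read_docking_table",
    "write_results",
]


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compound:
    """One compound record: ADMET properties as reported by a TCMSP-style table.

    ``ob`` is oral bioavailability in percent (>= 0); ``dl`` is the
    drug-likeness score in [0, 1].
    """

    mol_id: str
    name: str
    ob: float
    dl: float

    def __post_init__(self) -> None:
        if not self.mol_id:
            raise ValueError("mol_id must be non-empty")
        if self.ob < 0:
            raise ValueError(f"OB must be >= 0, got {self.ob}")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"DL must be in [0, 1], got {self.dl}")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: trimmed and uppercased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized gene symbols."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        normalized = frozenset(
            s for s in (normalize_symbol(g) for g in genes) if s
        )
        return cls(name=name, genes=normalized)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True)
class CentralityRecord:
    """The six per-node centrality scores used by the hub screen.

    Column order mirrors the CytoNCA export convention:
    betweenness, closeness, degree, eigenvector, LAC, network (NC).
    """

    node: str
    betweenness: float
    closeness: float
    degree: int
    eigenvector: float
    lac: float
    network: float

    COLUMNS = ("name", "Betweenness", "Closeness", "Degree",
               "Eigenvector", "LAC", "Network")

    def as_row(self) -> tuple:
        return (self.node, self.betweenness, self.closeness, self.degree,
                self.eigenvector, self.lac, self.network)


@dataclass(frozen=True)
class EnrichmentRow:
    """One annotation term's over-representation result.

    k of the n query genes fall in the term (term size K within a universe
    of N genes); ``p`` is the hypergeometric upper-tail probability and
    ``q`` its Benjamini-Hochberg adjustment across all tested terms.
    """

    term: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float
    genes: tuple[str, ...]
    category: str = ""
    significant: bool = False

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n if self.n else 0.0


DOCKING_GOOD_MAX = -5.0    # kcal/mol: <= -5.0 counts as good binding
DOCKING_STRONG_MAX = -7.0  # kcal/mol: <= -7.0 counts as strong binding


def grade_energy(energy: float) -> str:
    """Grade a binding free energy (kcal/mol) into weak / good / strong bands.

    The bands are nested thresholds reported as mutually exclusive labels:
    strong iff energy <= -7.0, good iff -7.0 < energy <= -5.0, else weak.
    """
    if energy <= DOCKING_STRONG_MAX:
        return "strong"
    if energy <= DOCKING_GOOD_MAX:
        return "good"
    return "weak"


@dataclass(frozen=True)
class DockingRecord:
    """A ligand-receptor binding free energy (kcal/mol; negative = favorable)."""

    ligand: str
    receptor: str
    energy: float
    grade: str = ""

    def __post_init__(self) -> None:
        if self.grade and self.grade != grade_energy(self.energy):
            raise ValueError(
                f"grade {self.grade!r} inconsistent with energy {self.energy}"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_COMPOUND_COLUMN_ALIASES = {
    "mol_id": ("mol id", "mol_id", "molid", "id"),
    "name": ("molecule name", "name", "molecule", "compound"),
    "ob": ("ob", "ob (%)", "oral bioavailability"),
    "dl": ("dl", "drug likeness", "drug-likeness"),
}


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_compound_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[Compound]:
    """Read a TSV/CSV compound property table into Compound records.

    The header must provide id, name, OB and DL columns; matching is
    case-insensitive and common aliases are recognized.  ``column_map``
    overrides the mapping (logical field -> actual header name).
    Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    lower_to_actual = {c.strip().lower(): c for c in df.columns}

    resolved: dict[str, str] = {}
    for field_name, aliases in _COMPOUND_COLUMN_ALIASES.items():
        if column_map and field_name in column_map:
            actual = column_map[field_name]
            if actual not in df.columns:
                raise FormatError(
                    f"{path}: mapped column {actual!r} for {field_name!r} not found"
                )
            resolved[field_name] = actual
            continue
        for alias in aliases:
            if alias in lower_to_actual:
                resolved[field_name] = lower_to_actual[alias]
                break
        else:
            raise FormatError(
                f"{path}: missing required column for {field_name!r} "
                f"(accepted headers: {', '.join(aliases)})"
            )

    compounds: list[Compound] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        record = dict(zip(df.columns, row))
        mol_id = str(record[resolved["mol_id"]]).strip()
        name = str(record[resolved["name"]]).strip()
        try:
            ob = float(record[resolved["ob"]])
            dl = float(record[resolved["dl"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric OB/DL at row {i}") from exc
        if mol_id in seen:
            raise FormatError(f"{path}: duplicate mol_id {mol_id!r} at row {i}")
        seen.add(mol_id)
        compounds.append(Compound(mol_id=mol_id, name=name, ob=ob, dl=dl))
    return compounds


def write_compound_table(compounds: Sequence[Compound], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.mol_id, c.name, c.ob, c.dl) for c in compounds],
        columns=["mol_id", "name", "OB", "DL"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; '#' starts a comment line."""
    path = Path(path)
    symbols: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(line)
    return GeneSet.from_iterable(name or path.stem, symbols)


def write_gene_list(genes: GeneSet | Iterable[str], path: str | Path) -> None:
    symbols = sorted(genes.genes if isinstance(genes, GeneSet) else set(genes))
    Path(path).write_text("".join(s + "\n" for s in symbols))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT annotation file: name, description, genes (tab-separated)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: GMT line {lineno} has {len(fields)} fields (need >= 3)"
                )
            name, _description, *genes = fields
            sets.append(GeneSet.from_iterable(name, genes))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column TSV edge list or a three-column SIF file.

    The dialect is auto-detected per row by column count (SIF carries an
    interaction label in the middle column).  The result is a simple
    undirected graph: duplicate and reversed pairs collapse, self-loops are
    dropped with a warning.
    """
    path = Path(path)
    g: nx.Graph = nx.Graph()
    dropped_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            # tab-delimited if tabs present (node names may contain spaces);
            # otherwise whitespace-delimited (plain SIF convention)
            if "\t" in line:
                fields = [f.strip() for f in line.split("\t") if f.strip()]
            else:
                fields = line.split()
            if len(fields) == 1:
                raise FormatError(
                    f"{path}: line {lineno} has a single column; need an edge"
                )
            if len(fields) == 2:
                endpoints = [(fields[0], fields[1])]
            else:  # SIF: source, interaction label, one or more targets
                u, _label, *targets = fields
                endpoints = [(u, t) for t in targets]
            for u, v in endpoints:
                if u == v:
                    dropped_loops += 1
                else:
                    g.add_edge(u, v)
    if dropped_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, dropped_loops)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write a graph as a canonical two-column TSV (sorted endpoint pairs)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in g.edges()):
            fh.write(f"{u}\t{v}\n")


def read_target_map(path: str | Path) -> dict[str, GeneSet]:
    """Read a compound-to-target map from two-column TSV pairs."""
    path = Path(path)
    pairs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno} needs two tab-separated columns"
                )
            compound, gene = fields[0].strip(), fields[1]
            pairs.setdefault(compound, set()).add(gene)
    return {
        c: GeneSet.from_iterable(c, genes) for c, genes in pairs.items()
    }


def write_target_map(target_map: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for compound in sorted(target_map):
            for gene in sorted(target_map[compound].genes):
                fh.write(f"{compound}\t{gene}\n")


def read_docking_table(path: str | Path) -> list[DockingRecord]:
    """Read a ligand/receptor/energy TSV into ungraded DockingRecords."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = {"ligand", "receptor", "energy"}
    missing = required - {c.strip().lower() for c in df.columns}
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    df.columns = [c.strip().lower() for c in df.columns]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            energy = float(row.energy)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric energy at row {i}") from exc
        records.append(DockingRecord(str(row.ligand), str(row.receptor), energy))
    return records


# ---------------------------------------------------------------------------
# Generic writer
# ---------------------------------------------------------------------------

def write_results(obj, path: str | Path) -> None:
    """Write a pipeline product to disk by type.

    Tables of dataclass records become CSV, graphs become two-column TSV,
    and mappings become JSON.  Output is bit-stable for identical inputs.
    """
    path = Path(path)
    if isinstance(obj, nx.Graph):
        write_edge_list(obj, path)
        return
    if isinstance(obj, Mapping):
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return
    if isinstance(obj, Sequence) and obj and dataclasses.is_dataclass(obj[0]):
        if isinstance(obj[0], CentralityRecord):
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(CentralityRecord.COLUMNS)
                writer.writerows(r.as_row() for r in obj)
        else:
            rows = [dataclasses.asdict(r) for r in obj]
            pd.DataFrame(rows).to_csv(path, index=False)
        return
    if isinstance(obj, Sequence):
        pd.DataFrame(list(obj)).to_csv(path, index=False)
        return
    raise TypeError(f"no writer for object of type {type(obj).__name__}")
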