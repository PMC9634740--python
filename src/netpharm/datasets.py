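"""Packaged reference fixtures.

Small published tables that ship with the package: the 22-compound ADMET
table, the 11-gene hub-subnetwork centrality table, the top-10 docking
energies, and the published median-screen threshold sextuples (reference
values only — the original screen-scale network is not redistributable).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .io_model import Compound, DockingRecord, read_compound_table, read_docking_table

__all__ = [
    "fixture_path",
    "load_compound_table",
    "load_hub_centrality_table",
    "load_docking_top10",
    "load_published_screen_thresholds",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("netpharm").joinpath("data", name))


def load_compound_table() -> list[Compound]:
    """The published 22-compound ADMET property table."""
    return read_compound_table(fixture_path("table1_compounds.tsv"))


def load_hub_centrality_table() -> dict[str, dict[str, float]]:
    """Published six-measure centrality scores of the 11 hub genes.

    Returns {gene: {betweenness, closeness, degree, eigenvector, lac,
    network}}; the degree column fixes the hub subnetwork's edge count
    (degrees sum to twice the number of edges).
    """
    path = fixture_path("table2_centralities.tsv")
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        keys = [h.strip().lower() for h in header[1:]]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields[0]:
                continue
            out[fields[0]] = dict(zip(keys, (float(x) for x in fields[1:])))
    return out


def load_docking_top10() -> list[DockingRecord]:
    """The published ten best ligand-receptor binding energies (ungraded)."""
    return read_docking_table(fixture_path("fig8_docking_top10.tsv"))


def load_published_screen_thresholds() -> dict:
    """Published round-1/round-2 median-screen thresholds (reference only).

    These sextuples were computed on the original screen-scale interaction
    network, which cannot be re-derived here; they are shipped for
    documentation and are not a computational target.
    """
    with open(fixture_path("published_screen_thresholds.json")) as fh:
        return json.load(fh)
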