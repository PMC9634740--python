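"""Grading and ranking of ligand-receptor binding-energy matrices.

Binding free energies (kcal/mol, more negative = stronger predicted
affinity) are graded into three bands: strong (<= -7.0), good
(-7.0 < E <= -5.0) and weak (otherwise).  Energies are inputs — a published
matrix or a synthetic one — this module never runs a docking engine.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

import pandas as pd

from .io_model import DockingRecord, grade_energy

logger = logging.getLogger("netpharm")

__all__ = ["grade_energies", "rank_pairs", "energy_matrix"]


def grade_energies(records: Sequence[DockingRecord]) -> list[DockingRecord]:
    """Assign affinity grades from energies; idempotent on graded input."""
    graded = [
        DockingRecord(r.ligand, r.receptor, r.energy, grade_energy(r.energy))
        for r in records
    ]
    counts = Counter(r.grade for r in graded)
    logger.info(
        "docking grades: %d strong, %d good, %d weak",
        counts.get("strong", 0), counts.get("good", 0), counts.get("weak", 0),
    )
    return graded


def rank_pairs(
    records: Sequence[DockingRecord], top_n: int = 10
) -> list[DockingRecord]:
    """The top_n records by ascending energy (most favorable first).

    Ties are broken by (ligand, receptor) lexicographically for
    deterministic output.
    """
    ordered = sorted(records, key=lambda r: (r.energy, r.ligand, r.receptor))
    return ordered[:top_n]


def energy_matrix(records: Sequence[DockingRecord]) -> pd.DataFrame:
    """Dense ligand x receptor energy matrix; missing pairs are NaN.

    Rows (ligands) and columns (receptors) are sorted for stable CSV export
    suitable for heatmap plotting.
    """
    df = pd.DataFrame(
        [(r.ligand, r.receptor, r.energy) for r in records],
        columns=["ligand", "receptor", "energy"],
    )
    if df.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate ligand-receptor pair in docking records")
    matrix = df.pivot(index="ligand", columns="receptor", values="energy")
    return matrix.sort_index(axis=0).sort_index(axis=1)
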