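"""Disease-source unions, Venn-region tallies, and drug-disease intersection.

Disease genes are typically collected from several curated databases whose
lists partially overlap; the union forms the disease target set.  The
candidate therapeutic targets are the genes the screened compounds hit that
also belong to that disease set — the per-compound restriction of the drug
target map to the disease union, and its global union.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

from .io_model import GeneSet

logger = logging.getLogger("netpharm")

__all__ = ["union_sources", "venn_regions", "intersect_drug_disease"]


def union_sources(sources: Sequence[GeneSet], name: str = "union") -> GeneSet:
    """Set union of normalized source gene sets."""
    merged: set[str] = set()
    for src in sources:
        merged |= src.genes
    logger.info(
        "merged %d source(s) into %d unique genes", len(sources), len(merged)
    )
    return GeneSet(name=name, genes=frozenset(merged))


def venn_regions(sources: Sequence[GeneSet]) -> dict[str, int]:
    """Exclusive Venn-region counts over 2-5 sources.

    One entry per non-empty membership pattern (2^k - 1 regions): a gene in
    exactly sources A and B counts toward region "A∩B"; a gene in A alone
    counts toward "A only".  Labels follow the input source order, so
    region counts sum to the union size.
    """
    if not 2 <= len(sources) <= 5:
        raise ValueError("venn_regions supports between 2 and 5 sources")
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        raise ValueError("source names must be unique")

    regions: dict[str, int] = {}
    index_combos = [
        combo
        for size in range(1, len(sources) + 1)
        for combo in combinations(range(len(sources)), size)
    ]
    for combo in index_combos:
        inside = set.intersection(*(set(sources[i].genes) for i in combo))
        outside: set[str] = set()
        for i in range(len(sources)):
            if i not in combo:
                outside |= sources[i].genes
        label = (
            f"{names[combo[0]]} only"
            if len(combo) == 1
            else "∩".join(names[i] for i in combo)
        )
        regions[label] = len(inside - outside)
    return regions


def intersect_drug_disease(
    drug_targets: Mapping[str, GeneSet],
    disease: GeneSet,
) -> tuple[GeneSet, dict[str, GeneSet]]:
    """Intersect per-compound drug targets with the disease gene set.

    Returns the global intersection (the union of all per-compound hits
    within the disease set) and the per-compound restricted target sets,
    which later seed the bipartite component-target network.
    """
    per_compound = {
        compound: GeneSet(
            name=compound, genes=frozenset(targets.genes & disease.genes)
        )
        for compound, targets in drug_targets.items()
    }
    merged: set[str] = set()
    for restricted in per_compound.values():
        merged |= restricted.genes
    logger.info(
        "drug-disease intersection: %d gene(s) across %d compound(s)",
        len(merged), len(per_compound),
    )
    return GeneSet(name="drug∩disease", genes=frozenset(merged)), per_compound
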