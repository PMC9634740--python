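"""Hypergeometric over-representation analysis with BH q-values.

Given a query gene set (here: drug-disease intersection genes), a
collection of annotation terms (GO / KEGG style gene sets) and a gene
universe, each term is tested for over-representation with the
hypergeometric upper tail, and p-values are adjusted across all tested
terms by the Benjamini-Hochberg step-up.  Terms with zero query overlap
are excluded from testing (and from the BH denominator) by default,
matching the reporting convention of the common ORA tools.
"""

from __future__ import annotations

import logging
from math import exp, lgamma, log
from typing import Iterable, Mapping, Sequence

from statsmodels.stats.multitest import multipletests

from .io_model import EnrichmentRow, GeneSet

logger = logging.getLogger("netpharm")

__all__ = ["hypergeom_tail", "bh_adjust", "run_ora", "top_n_report"]


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the annotated (term) genes, n the query size
    and k the observed overlap.  The tail is accumulated term-by-term in
    log space, which keeps small probabilities accurate to well over ten
    significant digits at ORA scales.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(
            f"impossible counts: k={k} must lie in [0, min(n={n}, K={K})]"
        )
    if n > N or K > N:
        raise ValueError(f"n={n} and K={K} cannot exceed N={N}")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    upper = min(n, K)
    lower = max(k, n - (N - K))  # below this the draw is impossible
    if lower > upper:
        return 0.0
    # factor out the max log for stability
    log_terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
        for i in range(lower, upper + 1)
    ]
    m = max(log_terms)
    total = sum(exp(t - m) for t in log_terms)
    return min(1.0, exp(m + log(total)))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    if len(pvals) == 0:
        return []
    _, q, _, _ = multipletests(list(pvals), method="fdr_bh")
    return [float(v) for v in q]


def run_ora(
    query: GeneSet,
    terms: Sequence[GeneSet],
    universe: GeneSet | None = None,
    q_max: float = 0.05,
    category: str = "",
    include_zero_overlap: bool = False,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` in each annotation term.

    The universe defaults to the union of all genes annotated to at least
    one term.  Query genes outside the universe are dropped with a warning;
    terms are intersected with the universe.  One row is returned per term
    with overlap k >= 1 (or per term, if ``include_zero_overlap``); q-values
    are BH-adjusted over exactly the tested terms.  Rows with q <= q_max
    are flagged significant; output is sorted by (p asc, term name asc).
    """
    if universe is None:
        universe = GeneSet.from_iterable(
            "universe", (g for t in terms for g in t.genes)
        )
    if len(universe) == 0:
        raise ValueError("enrichment universe is empty")

    query_in = query.genes & universe.genes
    dropped = len(query.genes) - len(query_in)
    if dropped:
        logger.warning(
            "ORA: %d query gene(s) outside the universe were dropped", dropped
        )
    n = len(query_in)
    N = len(universe)

    tested: list[tuple[GeneSet, frozenset[str], int]] = []
    for term in terms:
        term_genes = term.genes & universe.genes
        overlap = term_genes & query_in
        if overlap or include_zero_overlap:
            tested.append((term, frozenset(overlap), len(term_genes)))

    pvals = [
        hypergeom_tail(len(overlap), n, K, N) for _, overlap, K in tested
    ]
    qvals = bh_adjust(pvals)

    rows = [
        EnrichmentRow(
            term=term.name,
            k=len(overlap),
            n=n,
            K=K,
            N=N,
            p=p,
            q=q,
            genes=tuple(sorted(overlap)),
            category=category,
            significant=q <= q_max,
        )
        for (term, overlap, K), p, q in zip(tested, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def top_n_report(
    rows: Iterable[EnrichmentRow],
    per_category: Mapping[str, int],
) -> dict[str, list[EnrichmentRow]]:
    """Per category, the N lowest-p significant rows (ties broken by term name).

    Categories follow the GO/KEGG reporting convention (e.g. top 10 per GO
    ontology, top 30 KEGG pathways); each row's ``gene_ratio`` (k/n) is the
    dot-plot x-axis quantity.
    """
    by_category: dict[str, list[EnrichmentRow]] = {}
    for row in rows:
        by_category.setdefault(row.category, []).append(row)
    report: dict[str, list[EnrichmentRow]] = {}
    for cat, n_top in per_category.items():
        significant = [r for r in by_category.get(cat, []) if r.significant]
        significant.sort(key=lambda r: (r.p, r.term))
        report[cat] = significant[:n_top]
    return report
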