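# Methods

## Pipeline model and assumptions

The package implements a five-stage screening chain over set- and
graph-valued data. Gene identity is purely symbolic: symbols are
normalized by trimming and uppercasing only, with no alias resolution, so
all inputs are assumed to carry already-standardized gene symbols. Graphs
are simple and undirected throughout; self-loops in input edge lists are
dropped (with a warning) and duplicate/reversed pairs collapse on read.

### ADMET screen

Compounds pass when OB ≥ `ob_min` (default 30 %) **and** DL ≥ `dl_min`
(default 0.18), both inclusive — the conventional cutoffs for
herbal-compound eligibility. The filter is order-preserving, idempotent
and monotone in both thresholds.

### Target sets

The disease set is the plain union of the per-source gene sets. Venn
regions are exclusive membership patterns (2^k − 1 labels, in input source
order), so region counts always sum to the union size. No background
universe is imposed at this stage; the enrichment universe is chosen
separately, mirroring the order of the original workflow.

### Over-representation analysis

* p-value: hypergeometric upper tail P(X ≥ k), accumulated in log space
  via `lgamma` with the maximum log term factored out. On universes up to
  N = 12 the implementation agrees with exhaustive draw enumeration to
  10 significant digits (tested), and with `scipy.stats.hypergeom.sf` at
  realistic ORA scales.
* q-value: Benjamini–Hochberg adjusted p (not Storey's estimator), the
  default reporting convention of the common ORA tools; computed via
  statsmodels behind the module surface and cross-checked against a hand
  step-up in tests.
* Terms with zero query overlap are not tested and do not enter the BH
  denominator (switchable with `include_zero_overlap=True`). The universe
  defaults to all genes annotated to ≥ 1 term; query genes outside the
  universe are dropped with a warning.
* Significance defaults to q ≤ 0.05; the flag is exposed because published
  figure-selection rules sometimes mix p- and q-thresholds. Top-N
  reporting breaks p ties by term name for determinism.

### Network topology

The six centralities follow the CytoNCA measure definitions:

* **betweenness** — unnormalized Brandes accumulation; each unordered
  pair counted once (a normalized variant is exposed but not default,
  since published screen thresholds imply raw counts);
* **closeness** — (r−1)/S over the r reachable nodes at total distance S,
  scaled by (r−1)/(n−1) on disconnected graphs so small components do not
  outrank the main one (the target use case is connected; the correction
  is a documented extension), 0 for isolated nodes;
* **eigenvector** — power iteration on A + I (same eigenvectors as A; the
  shift breaks the ± eigenvalue symmetry of bipartite graphs that stalls
  plain iteration), relative tolerance 1e−10, cap 10⁴ iterations,
  non-convergence raising an error that names both; computed on the
  largest connected component, zeros elsewhere, sign fixed nonnegative,
  unit Euclidean norm. Only orderings matter to the median screen, so the
  normalization choice does not affect screening;
* **LAC** and **NC** as defined in the README; ECC denominators of 0 give
  ECC = 0.

**Median screen.** Each round computes all six measures on the current
graph, thresholds at the per-measure median (standard convention: mean of
the two middle order statistics for even n), retains nodes with all six
values **≥** their medians, and recurses on the induced subgraph.
The ≥ convention is deliberate: a published hub table retains several
nodes sitting exactly at the degree threshold, which > would discard.
Survivors are ordered by degree descending, then name. A round with zero
survivors stops the iteration and is flagged (`stopped_early`).

**Degree-sequence reconstruction.** When only a published per-node degree
column is available (no edge list), `graph_from_degree_sequence` realizes
it as a concrete simple graph by Havel–Hakimi. Any realization of the
11-gene hub table's column has 45 edges, one universal node, and minimum
degree 7 — enough to force the analytic checks used in the tests
(closeness 1, 10/11, 10/12, 10/13; LAC 7; NC 10). Quantities that depend
on the exact wiring (e.g. betweenness) are not asserted against the
published table, and the published round-1/round-2 screen thresholds ship
as a reference JSON only: they were computed on a screen-scale network
export that cannot be reconstructed from the published material (its
round-2 betweenness value is in fact inconsistent with the published hub
table, and is recorded as printed).

### Docking summary

Grades are a pure function of energy — strong iff E ≤ −7.0 kcal/mol, good
iff −7.0 < E ≤ −5.0, weak otherwise. The thresholds are nested bounds
reported as mutually exclusive bands. Ranking is ascending by energy with
(ligand, receptor) lexicographic tie-breaks, which reproduces the packaged
published top-10 ordering exactly. Energies are always inputs; no docking
engine is run.

## Synthetic data: what it emulates, and what it does not

One integer seed drives a named sub-stream per generator (seed plus a
CRC32 of the stream name), so adding a generator never perturbs existing
outputs and a fixed config is byte-identical across runs.

| parameter | default | meaning |
|---|---|---|
| `n_compounds` | 200 | compound table rows |
| `frac_pass` | 0.5 | expected joint ADMET pass fraction; OB/DL means derived so each axis passes with √frac_pass |
| `ob_sd`, `dl_sd` | 15 %, 0.15 | spread of the property distributions |
| `n_universe` | 3000 | desk-scale gene universe |
| `source_sizes` | 800/300/150/100 | four disease sources: one large aggregator plus three curated lists |
| `pairwise_overlap` | 0.2 | shared-core size ≈ overlap × mean source size |
| `targets_per_compound` | 5–40 | uniform per-compound target count |
| `disease_target_frac` | 0.3 | fraction of targets drawn from the disease union (intersection non-empty by construction) |
| `n_terms`, `n_enriched_terms` | 200, 5 | annotation terms; planted terms oversample the signal genes `enrichment_strength`-fold (default 8) |
| `term_size_range` | 20–200 | uniform term sizes |
| `ppi_nodes`, `ppi_edge_prob` | 117, 0.05 | Erdős–Rényi backbone |
| `n_hubs`, `hub_degree_boost` | 11, 20 | planted hubs, extra random neighbors each |

OB/DL clamping (at 0, and [0, 1]) only moves values that fail the filter
anyway, so the pass-fraction calibration is exact in expectation.

The generator reproduces the *statistical* structure the pipeline relies
on — overlap between sources, a non-empty drug–disease intersection,
over-represented terms, degree-outlier hubs — and none of the biology:
no real symbols, no chemistry, no PPI topology beyond ER-plus-hubs (real
interactomes are heavy-tailed and clustered). Passing tests therefore
demonstrate that the algorithms recover planted structure under the
assumed model, not that any particular biological claim holds; runs on
real exports are supported through the same file formats.

Hub recovery is intentionally not perfect: with a boost of 20 on a
backbone with mean degree ≈ 5.8, most planted hubs dominate every
measure, but a hub can land below a triangle-based median by chance. The
fixed-seed recovery checks assert ≥ 9 of 11 hubs after two rounds.

## Numerical and design choices

* Exact arithmetic where possible (set operations, degree, LAC/NC as
  rationals of integers); floating-point only in closeness, betweenness
  divisions, eigenvector iteration and the hypergeometric tail.
* All table output uses `.` decimals and no thousands separators (the
  packaged hub table stores published comma-grouped values with the
  grouping stripped, treating it as formatting noise).
* Determinism everywhere: sorted iteration orders, explicit tie-breaks,
  seeded RNG sub-streams, canonical (sorted, two-column TSV) edge-list
  output that round-trips through the reader.
* The pipeline orchestrator aborts on the first failing stage, naming the
  stage, and keeps any artifacts already written; an empty drug–disease
  intersection skips the downstream stages with a notice instead of
  failing.
* Problem sizes in tests are chosen desk-scale: the oracle-equivalence
  suite enumerates all 143 connected graphs on ≤ 6 nodes, the
  hypergeometric scan covers every parameter combination with N ≤ 12, and
  pipeline tests use a reduced synthetic config (25 compounds, 400-gene
  universe, 40-node PPI).

## Known limitations

* No gene-symbol alias resolution or ID mapping; inputs must be
  pre-normalized.
* The closeness component correction and the eigenvector normalization
  are conventions; other tools differ on disconnected graphs.
* `graph_from_degree_sequence` returns one Havel–Hakimi realization, not
  a uniform sample of graphs with that degree sequence.
* Published enriched-term counts from annotation-version-dependent runs
  (GO/KEGG release specific) and live docking energies are out of scope
  by design; only classification/ranking of a given energy matrix is
  implemented.
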