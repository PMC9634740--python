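"""PPI-network topology: six centrality measures and the iterative median hub screen.

The hub-screening procedure ranks every node of an undirected
protein-protein interaction graph by six measures — betweenness, closeness,
degree, eigenvector, local average connectivity (LAC) and edge-clustering
network centrality (NC) — then repeatedly retains only the nodes whose
scores are at or above the per-measure median, inducing the subgraph on the
survivors between rounds.  Two rounds of this median filter reduce a
screen-scale interaction network to a small hub subnetwork.

All six measures are computed here from first principles (the measure
definitions follow the CytoNCA conventions):

* betweenness is the raw (unnormalized) Brandes accumulation with each
  unordered pair counted once;
* closeness is (r-1)/S for r reachable nodes at total distance S, with a
  component-size correction factor (r-1)/(n-1) on disconnected graphs;
* eigenvector centrality is the nonnegative principal adjacency eigenvector
  (power iteration, unit Euclidean norm), computed on the largest connected
  component with zeros elsewhere;
* LAC(v) is the mean degree of v's neighbors within the subgraph induced on
  the neighborhood;
* NC(v) sums the edge clustering coefficient ECC(v,u) = z / min(deg v - 1,
  deg u - 1) over v's incident edges, where z counts triangles on the edge.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .io_model import CentralityRecord, GeneSet

__all__ = [
    "build_bipartite",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "lac_centrality",
    "network_centrality",
    "centrality_table",
    "median_screen",
    "ScreenRound",
    "ConvergenceError",
    "graph_from_degree_sequence",
    "MEASURES",
]

MEASURES = ("betweenness", "closeness", "degree", "eigenvector", "lac", "network")


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach its tolerance within the iteration cap."""


# ---------------------------------------------------------------------------
# Bipartite component-target network
# ---------------------------------------------------------------------------

def build_bipartite(per_compound_targets: Mapping[str, GeneSet]) -> nx.Graph:
    """Build the bipartite compound-target network.

    One edge per (compound, target) pair; node roles are tagged with the
    ``role`` attribute ("compound" or "target").  Compound degree in this
    graph is the number of disease-relevant genes the compound hits, the
    quantity used to rank active components.
    """
    g: nx.Graph = nx.Graph()
    for compound, targets in per_compound_targets.items():
        g.add_node(compound, role="compound")
        for gene in targets.genes:
            g.add_node(gene, role="target")
            g.add_edge(compound, gene)
    return g


# ---------------------------------------------------------------------------
# Centrality measures
# ---------------------------------------------------------------------------

def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Neighbor count per node."""
    return {v: g.degree(v) for v in g.nodes}


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Closeness per node: (r-1)/S over the r reachable nodes at distance sum S.

    On disconnected graphs the value is scaled by (r-1)/(n-1) so that nodes
    in small components do not outrank central nodes of the main component;
    isolated nodes score 0.
    """
    n = g.number_of_nodes()
    out: dict[str, float] = {}
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        r = len(lengths)  # includes v itself
        total = sum(lengths.values())
        if r <= 1 or total == 0:
            out[v] = 0.0
            continue
        closeness = (r - 1) / total
        if r < n:  # component-size correction on disconnected graphs
            closeness *= (r - 1) / (n - 1)
        out[v] = closeness
    return out


def betweenness_centrality(g: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Raw shortest-path betweenness (Brandes accumulation).

    Each unordered node pair contributes once; endpoints are excluded.
    With ``normalized=True`` values are divided by (n-1)(n-2)/2.
    """
    bc: dict[str, float] = dict.fromkeys(g.nodes, 0.0)
    for s in g.nodes:
        # single-source stage: BFS with path counting
        stack: list = []
        preds: dict = {v: [] for v in g.nodes}
        sigma: dict = dict.fromkeys(g.nodes, 0.0)
        dist: dict = dict.fromkeys(g.nodes, -1)
        sigma[s] = 1.0
        dist[s] = 0
        queue = [s]
        while queue:
            v = queue.pop(0)
            stack.append(v)
            for w in g.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # back-propagation of pair dependencies
        delta: dict = dict.fromkeys(g.nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # every unordered pair was visited from both endpoints
    for v in bc:
        bc[v] /= 2.0
    if normalized:
        n = g.number_of_nodes()
        scale = (n - 1) * (n - 2) / 2.0
        if scale > 0:
            for v in bc:
                bc[v] /= scale
    return bc


def eigenvector_centrality(
    g: nx.Graph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Principal adjacency eigenvector, nonnegative, unit Euclidean norm.

    Computed by power iteration on the largest connected component (where
    Perron-Frobenius guarantees a unique nonnegative principal vector);
    nodes outside that component score 0.
    """
    out: dict[str, float] = dict.fromkeys(g.nodes, 0.0)
    if g.number_of_nodes() == 0:
        return out
    component = max(nx.connected_components(g), key=len)
    nodes = sorted(component)
    if len(nodes) == 1 or g.subgraph(nodes).number_of_edges() == 0:
        # a single node (or edgeless component) has eigenvalue 0; the
        # centrality is conventionally its unit vector
        for v in nodes:
            out[v] = 1.0 / np.sqrt(len(nodes))
        return out
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in g.subgraph(nodes).edges():
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    # iterate on A + I: same eigenvectors, but the shift breaks the +/-
    # eigenvalue symmetry of bipartite graphs that stalls plain iteration
    a += np.eye(len(nodes))
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        x_next = a @ x
        norm = np.linalg.norm(x_next)
        x_next /= norm
        if np.linalg.norm(x_next - x) < tol * np.linalg.norm(x_next):
            x = x_next
            break
        x = x_next
    else:
        raise ConvergenceError(
            f"power iteration did not reach relative tolerance {tol} "
            f"within {max_iter} iterations"
        )
    x = np.abs(x)  # Perron vector is nonnegative; fix sign convention
    x /= np.linalg.norm(x)
    for v, i in index.items():
        out[v] = float(x[i])
    return out


def lac_centrality(g: nx.Graph) -> dict[str, float]:
    """Local average connectivity: mean within-neighborhood degree of neighbors.

    LAC(v) = (sum over u in N(v) of the degree of u in the subgraph induced
    on N(v)) / |N(v)|; 0 for degree-0 nodes.  Equivalently twice the edge
    count among the neighbors divided by the neighbor count.
    """
    out: dict[str, float] = {}
    adjacency = {v: set(g.neighbors(v)) for v in g.nodes}
    for v in g.nodes:
        neigh = adjacency[v]
        if not neigh:
            out[v] = 0.0
            continue
        internal_degree_sum = sum(
            len(adjacency[u] & neigh) for u in neigh
        )
        out[v] = internal_degree_sum / len(neigh)
    return out


def network_centrality(g: nx.Graph) -> dict[str, float]:
    """NC(v): sum of edge clustering coefficients over v's incident edges.

    ECC(v,u) = z(v,u) / min(deg v - 1, deg u - 1) with z the number of
    triangles containing the edge; ECC is 0 when the denominator is 0.
    """
    out: dict[str, float] = {}
    adjacency = {v: set(g.neighbors(v)) for v in g.nodes}
    for v in g.nodes:
        total = 0.0
        deg_v = len(adjacency[v])
        for u in adjacency[v]:
            denom = min(deg_v - 1, len(adjacency[u]) - 1)
            if denom > 0:
                total += len(adjacency[v] & adjacency[u]) / denom
        out[v] = total
    return out


def compute_all_centralities(g: nx.Graph) -> dict[str, dict[str, float]]:
    """All six measures keyed by measure name."""
    return {
        "betweenness": betweenness_centrality(g),
        "closeness": closeness_centrality(g),
        "degree": degree_centrality(g),
        "eigenvector": eigenvector_centrality(g),
        "lac": lac_centrality(g),
        "network": network_centrality(g),
    }


def centrality_table(g: nx.Graph) -> list[CentralityRecord]:
    """All six measures for every node, ordered by degree desc then name."""
    scores = compute_all_centralities(g)
    records = [
        CentralityRecord(
            node=str(v),
            betweenness=scores["betweenness"][v],
            closeness=scores["closeness"][v],
            degree=int(scores["degree"][v]),
            eigenvector=scores["eigenvector"][v],
            lac=scores["lac"][v],
            network=scores["network"][v],
        )
        for v in g.nodes
    ]
    records.sort(key=lambda r: (-r.degree, r.node))
    return records


# ---------------------------------------------------------------------------
# Iterative median screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenRound:
    """Outcome of one median-filter round.

    ``thresholds`` holds the per-measure medians of the round's input graph;
    ``survivors`` are the nodes whose six scores all met their medians,
    ordered by degree descending then name; ``subgraph`` is induced on them.
    ``stopped_early`` marks a round that eliminated every node.
    """

    round_index: int
    thresholds: dict[str, float]
    survivors: list[str]
    subgraph: nx.Graph
    stopped_early: bool = False


def median_screen(g: nx.Graph, rounds: int = 2) -> list[ScreenRound]:
    """Iterative per-measure median filtering on all six centralities.

    Each round computes the six centralities on the current graph, takes the
    median of each measure over the current nodes (standard median: mean of
    the two middle order statistics for even counts), and retains exactly
    the nodes whose scores are >= the median on ALL six measures.  The
    subgraph induced on the survivors feeds the next round.  Retention uses
    >= so that nodes sitting exactly at a threshold survive.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("median_screen requires a non-empty graph")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")

    results: list[ScreenRound] = []
    current = g
    for r in range(1, rounds + 1):
        scores = compute_all_centralities(current)
        thresholds = {
            m: float(statistics.median(scores[m][v] for v in current.nodes))
            for m in MEASURES
        }
        survivors = [
            v for v in current.nodes
            if all(scores[m][v] >= thresholds[m] for m in MEASURES)
        ]
        survivors.sort(key=lambda v: (-scores["degree"][v], str(v)))
        sub = current.subgraph(survivors).copy()
        if not survivors:
            results.append(ScreenRound(r, thresholds, [], sub, stopped_early=True))
            break
        results.append(ScreenRound(r, thresholds, survivors, sub))
        current = sub
    return results


# ---------------------------------------------------------------------------
# Degree-sequence reconstruction (Havel-Hakimi)
# ---------------------------------------------------------------------------

def graph_from_degree_sequence(degrees: Mapping[str, int]) -> nx.Graph:
    """Build a simple graph realizing a named degree sequence (Havel-Hakimi).

    Used to reconstruct a concrete hub subnetwork from a published per-node
    degree column when the edge list itself is unavailable.  Raises
    ValueError if the sequence is not graphical.
    """
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(degrees)
    remaining = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    remaining = [[d, v] for v, d in remaining]
    while remaining:
        remaining.sort(key=lambda dv: (-dv[0], dv[1]))
        d, v = remaining.pop(0)
        if d == 0:
            continue
        if d > len(remaining):
            raise ValueError("degree sequence is not graphical")
        for entry in remaining[:d]:
            if entry[0] == 0:
                raise ValueError("degree sequence is not graphical")
            g.add_edge(v, entry[1])
            entry[0] -= 1
    return g
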