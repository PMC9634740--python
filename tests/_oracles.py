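"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first definitions (adjacency matrices,
exhaustive path enumeration, dense eigendecomposition, combinatorial
enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def adjacency(nodes: list, edges: list) -> np.ndarray:
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in edges:
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    return a


def distance_matrix(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by repeated boolean matrix products."""
    n = len(a)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = np.eye(n, dtype=bool)
    power = np.eye(n, dtype=bool)
    adj = a > 0
    for step in range(1, n):
        power = power @ adj
        newly = power & ~reach
        dist[newly] = step
        reach |= newly
    return dist


def brute_degree(nodes, edges):
    a = adjacency(nodes, edges)
    return {v: int(a[i].sum()) for i, v in enumerate(nodes)}


def brute_closeness(nodes, edges):
    a = adjacency(nodes, edges)
    dist = distance_matrix(a)
    n = len(nodes)
    out = {}
    for i, v in enumerate(nodes):
        finite = dist[i][np.isfinite(dist[i])]
        r = len(finite)  # includes v itself
        total = finite.sum()
        if r <= 1 or total == 0:
            out[v] = 0.0
            continue
        c = (r - 1) / total
        if r < n:
            c *= (r - 1) / (n - 1)
        out[v] = c
    return out


def _all_shortest_paths(nodes, edges, s, t):
    """Every shortest s-t path, found by exhaustive DFS over simple paths."""
    neighbors = {v: set() for v in nodes}
    for u, v in edges:
        neighbors[u].add(v)
        neighbors[v].add(u)
    best: list[list] = []
    best_len = [float("inf")]

    def dfs(path):
        v = path[-1]
        if len(path) - 1 > best_len[0]:
            return
        if v == t:
            if len(path) - 1 < best_len[0]:
                best_len[0] = len(path) - 1
                best.clear()
            if len(path) - 1 == best_len[0]:
                best.append(list(path))
            return
        for w in neighbors[v]:
            if w not in path:
                path.append(w)
                dfs(path)
                path.pop()

    dfs([s])
    return best


def brute_betweenness(nodes, edges):
    """Raw betweenness: fraction of shortest paths through v per unordered pair."""
    out = dict.fromkeys(nodes, 0.0)
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(nodes, edges, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def brute_eigenvector(nodes, edges):
    """Principal eigenvector of the largest component, by dense eigh."""
    a = adjacency(nodes, edges)
    # connected components via reachability
    dist = distance_matrix(a)
    unassigned = set(range(len(nodes)))
    components = []
    while unassigned:
        i = min(unassigned)
        comp = {j for j in unassigned if np.isfinite(dist[i, j])}
        components.append(sorted(comp))
        unassigned -= comp
    comp = max(components, key=len)
    out = dict.fromkeys(nodes, 0.0)
    sub = a[np.ix_(comp, comp)]
    if sub.sum() == 0:
        for j in comp:
            out[nodes[j]] = 1.0 / np.sqrt(len(comp))
        return out
    w, vecs = np.linalg.eigh(sub)
    principal = np.abs(vecs[:, np.argmax(w)])
    principal /= np.linalg.norm(principal)
    for j, idx in enumerate(comp):
        out[nodes[idx]] = float(principal[j])
    return out


def brute_lac(nodes, edges):
    """Induced-subgraph degree sums over each neighborhood."""
    a = adjacency(nodes, edges)
    index = {v: i for i, v in enumerate(nodes)}
    out = {}
    for v in nodes:
        neigh = [u for u in nodes if a[index[v], index[u]] > 0]
        if not neigh:
            out[v] = 0.0
            continue
        idx = [index[u] for u in neigh]
        sub = a[np.ix_(idx, idx)]
        out[v] = float(sub.sum()) / len(neigh)  # sum of induced degrees
    return out


def brute_network(nodes, edges):
    """Triangle counting per edge via A^2, summed as ECC over incident edges."""
    a = adjacency(nodes, edges)
    index = {v: i for i, v in enumerate(nodes)}
    a2 = a @ a
    deg = a.sum(axis=1)
    out = {}
    for v in nodes:
        i = index[v]
        total = 0.0
        for u in nodes:
            j = index[u]
            if a[i, j] > 0:
                denom = min(deg[i] - 1, deg[j] - 1)
                if denom > 0:
                    total += a2[i, j] / denom  # A^2[i,j] = common neighbors
        out[v] = total
    return out


def brute_hypergeom_tail_table(N: int, K: int, n: int) -> dict[int, float]:
    """P(X >= k) for every k, by enumerating all C(N, n) draws."""
    from math import comb

    population = range(N)
    annotated = set(range(K))
    tally = dict.fromkeys(range(min(n, K) + 1), 0)
    for draw in combinations(population, n):
        tally[len(annotated & set(draw))] += 1
    total = comb(N, n)
    tails = {}
    for k in range(min(n, K) + 1):
        tails[k] = sum(tally[i] for i in range(k, min(n, K) + 1)) / total
    return tails


def brute_bh(pvals):
    """Hand Benjamini-Hochberg step-up, in input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        value = pvals[i] * m / rank_from_end
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
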