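from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def connected_graphs_upto_6():
    """Every connected non-isomorphic graph on 1-6 nodes, string-labelled."""
    graphs = []
    for g in nx.graph_atlas_g():
        if 1 <= g.number_of_nodes() <= 6 and nx.is_connected(g):
            graphs.append(nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes}))
    assert len(graphs) == 1 + 1 + 2 + 6 + 21 + 112
    return graphs


@pytest.fixture()
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g
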