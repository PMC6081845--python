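import networkx as nx
import pytest

from atlasforge import CorrelationGraph, make_annotation_fixtures, make_truth
from atlasforge._rng import stream


@pytest.fixture(scope="session")
def small_truth():
    """2,000-gene Zipf baseline without planted structure."""
    return make_truth(2000, seed=3, n_clusters=0, cluster_size=0)


@pytest.fixture(scope="session")
def fixtures():
    return make_annotation_fixtures([f"G{i:03d}" for i in range(20)], seed=0)


def planted_partition(n_blocks=4, block_size=25, p_in=0.9, p_out=0.02, seed=42):
    """Random graph with known block structure, for clustering recovery."""
    rng = stream(seed, "planted-partition")
    g = nx.Graph()
    nodes = [f"n{i:03d}" for i in range(n_blocks * block_size)]
    g.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            same = i // block_size == j // block_size
            if rng.random() < (p_in if same else p_out):
                g.add_edge(nodes[i], nodes[j], weight=0.9 if same else 0.82)
    labels = [i // block_size for i in range(len(nodes))]
    return CorrelationGraph(g, 0.8), nodes, labels


@pytest.fixture(scope="session")
def planted_graph():
    return planted_partition()
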