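import networkx as nx
import numpy as np
import pytest

from netpep.graph_core import NetworkGraph


@pytest.fixture
def triangle() -> NetworkGraph:
    return NetworkGraph([("A", "B"), ("B", "C"), ("C", "A")], name="triangle")


@pytest.fixture
def path3() -> NetworkGraph:
    return NetworkGraph([("A", "B"), ("B", "C")], name="path3")


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> NetworkGraph:
    """Erdos-Renyi graph with string labels, reproducible from rng."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return NetworkGraph.from_networkx(nx.relabel_nodes(g, {i: f"N{i}" for i in range(n)}))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
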