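import networkx as nx
import numpy as np
import pytest

from cognav.multiplex import Layer, build_multiplex
from cognav.walks import FluencyList


@pytest.fixture
def chain_graph():
    """dog—home—cat—feline—lion: unique shortest paths between responses."""
    g = nx.Graph()
    g.add_edges_from([("dog", "home"), ("home", "cat"),
                      ("cat", "feline"), ("feline", "lion")])
    return g


@pytest.fixture
def chain_lvc():
    return frozenset({"dog", "home", "cat"})


@pytest.fixture
def chain_fluency():
    return FluencyList("p1", ["dog", "cat", "lion"])


def random_multiplex(rng: np.random.Generator, n_nodes: int, n_layers: int,
                     p: float):
    """Random multiplex: each layer an independent G(n, p) over one universe."""
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    layers = []
    for k in range(n_layers):
        edges = [(nodes[i], nodes[j])
                 for i in range(n_nodes) for j in range(i + 1, n_nodes)
                 if rng.random() < p]
        layers.append(Layer(f"layer{k}", edges, nodes))
    return build_multiplex(layers)


@pytest.fixture
def make_random_multiplex():
    return random_multiplex
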