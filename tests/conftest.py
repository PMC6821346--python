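import numpy as np
import pytest

from entoptlayout.graph_io import WeightedGraph
from entoptlayout.model import LayoutState


@pytest.fixture
def triangle() -> WeightedGraph:
    """Unweighted K3."""
    return WeightedGraph(["A", "B", "C"], {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0})


@pytest.fixture
def path3() -> WeightedGraph:
    """Unweighted path A-B-C."""
    return WeightedGraph(["A", "B", "C"], {(0, 1): 1.0, (1, 2): 1.0})


@pytest.fixture
def dyad() -> WeightedGraph:
    return WeightedGraph(["A", "B"], {(0, 1): 1.0})


def random_graph(n: int, seed: int, p_edge: float = 0.5) -> WeightedGraph:
    """Connected-ish random weighted graph for gradient/property checks."""
    rng = np.random.default_rng(seed)
    ids = [f"v{i}" for i in range(n)]
    edges = {}
    for i in range(n - 1):  # spanning path guarantees >= n-1 edges
        edges[(i, i + 1)] = float(rng.uniform(0.5, 2.0))
    for i in range(n):
        for j in range(i + 2, n):
            if rng.random() < p_edge:
                edges[(i, j)] = float(rng.uniform(0.5, 2.0))
    return WeightedGraph(ids, edges)


def random_layout(graph: WeightedGraph, seed: int) -> LayoutState:
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    return LayoutState(
        list(graph.node_ids),
        rng.random((n, 2)) * 2.0,
        rng.uniform(0.05, 0.4, n),
    )
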