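"""Seeded synthetic modular networks with ground-truth module labels.

Planted-partition (equal-block stochastic block model) graphs stand in for
modular interactomes: within-module pairs are connected with probability
``p_in``, between-module pairs with ``p_out < p_in``.  The deterministic
ring-of-cliques family gives a small, exactly known modular graph for
pipeline tests.  Sizes are kept modest because layout iterations cost
O(n^2) per step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .graph_io import WeightedGraph


@dataclass
class PlantedPartitionSpec:
    """Parameters of an equal-block planted-partition graph.

    ``weight_mode`` is ``"unit"`` (all weights 1) or ``"uniform"`` (weights
    drawn uniformly from [w_lo, w_hi)).
    """

    n_modules: int
    nodes_per_module: int
    p_in: float
    p_out: float
    weight_mode: str = "unit"
    w_lo: float = 0.5
    w_hi: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_modules < 1 or self.nodes_per_module < 1:
            raise ValueError("module counts must be positive")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1 for modular structure")
        if self.weight_mode not in ("unit", "uniform"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


def _node_name(k: int) -> str:
    return f"n{k:03d}"


def planted_partition(
    spec: PlantedPartitionSpec, require_connected: bool = True
) -> tuple[WeightedGraph, list[int]]:
    """Sample a planted-partition graph; returns (graph, per-node labels).

    Deterministic per seed.  When ``require_connected`` (the benchmark
    default), disconnected draws are retried with incremented seeds up to
    10 times before raising.
    """
    attempts = 10 if require_connected else 1
    for attempt in range(attempts):
        seed = (spec.seed + attempt) % 2**31
        rng = np.random.default_rng(seed)
        n = spec.n_modules * spec.nodes_per_module
        labels = [k // spec.nodes_per_module for k in range(n)]
        lab = np.asarray(labels)
        iu, ju = np.triu_indices(n, k=1)
        same = lab[iu] == lab[ju]
        prob = np.where(same, spec.p_in, spec.p_out)
        keep = rng.random(len(iu)) < prob
        if spec.weight_mode == "uniform":
            weights = rng.uniform(spec.w_lo, spec.w_hi, size=len(iu))
        else:
            weights = np.ones(len(iu))
        node_ids = [_node_name(k) for k in range(n)]
        edges = {
            (int(i), int(j)): float(w)
            for i, j, w in zip(iu[keep], ju[keep], weights[keep])
        }
        graph = WeightedGraph(node_ids=node_ids, edges=edges)
        if not require_connected or _is_connected(graph):
            return graph, labels
    raise RuntimeError(
        f"planted partition disconnected after {attempts} seed retries "
        f"(p_in={spec.p_in}, p_out={spec.p_out})"
    )


def _is_connected(graph: WeightedGraph) -> bool:
    return graph.n_nodes >= 1 and nx.is_connected(graph.to_networkx())


def ring_of_cliques(
    n_cliques: int, clique_size: int
) -> tuple[WeightedGraph, list[int]]:
    """Cliques joined in a ring by single bridge edges; fully deterministic.

    ``n_cliques * clique_size`` nodes, ``n_cliques * C(clique_size, 2) +
    n_cliques`` unit-weight edges.  Labels give clique membership.
    """
    if n_cliques < 3:
        raise ValueError("need at least 3 cliques for a ring")
    if clique_size < 3:
        raise ValueError("cliques must have at least 3 nodes")
    n = n_cliques * clique_size
    node_ids = [_node_name(k) for k in range(n)]
    labels = [k // clique_size for k in range(n)]
    edges: dict[tuple[int, int], float] = {}
    for c in range(n_cliques):
        base = c * clique_size
        for a in range(clique_size):
            for b in range(a + 1, clique_size):
                edges[(base + a, base + b)] = 1.0
    # bridge: last node of clique c to first node of clique c+1 (mod ring)
    for c in range(n_cliques):
        u = c * clique_size + (clique_size - 1)
        v = ((c + 1) % n_cliques) * clique_size
        key = (min(u, v), max(u, v))
        edges[key] = 1.0
    return WeightedGraph(node_ids=node_ids, edges=edges), labels


def write_benchmark(
    graph: WeightedGraph, labels, edge_path, label_path
) -> None:
    """Write a generated benchmark as edge-list TSV + labels CSV."""
    with open(edge_path, "w") as fh:
        for (i, j), w in sorted(graph.edges.items()):
            fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\t{w:g}\n")
    with open(label_path, "w") as fh:
        fh.write("node_id,module\n")
        for nid, lab in zip(graph.node_ids, labels):
            fh.write(f"{nid},{lab}\n")
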