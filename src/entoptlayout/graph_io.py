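"""Reading and writing networks and layouts.

Supported network formats: whitespace/tab edge lists (optional weight
column), SIF, and GraphML.  Layouts travel as node-table CSVs with columns
``node_id,x,y[,width]`` or as GraphML node attributes.  Node indexing is
deterministic: nodes are numbered in order of first appearance in the file.
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default Gaussian width assigned when a layout file has no width column.
DEFAULT_WIDTH = 0.1


class GraphFormatError(ValueError):
    """Raised for unparseable or invalid network/layout input."""


@dataclass
class WeightedGraph:
    """An undirected graph with positive edge weights.

    Parameters
    ----------
    node_ids
        Unique string identifiers, in a stable order (first appearance in
        the source file).  All matrix/vector quantities in this package are
        indexed consistently with this order.
    edges
        Mapping from unordered index pairs ``(i, j)`` with ``i < j`` to
        positive weights.  Self-loops are never stored.
    """

    node_ids: list[str]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"node {node_id!r} not in graph") from None

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric weight matrix W with zero diagonal."""
        n = self.n_nodes
        w = np.zeros((n, n))
        for (i, j), wt in self.edges.items():
            w[i, j] = wt
            w[j, i] = wt
        return w

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for (i, j), wt in self.edges.items():
            g.add_edge(self.node_ids[i], self.node_ids[j], weight=wt)
        return g

    @classmethod
    def from_edges(
        cls, edge_iter, *, warn_context: str = "input"
    ) -> "WeightedGraph":
        """Build a graph from an iterable of ``(u, v, weight)`` triples.

        Node order follows first appearance.  Duplicate undirected edges are
        merged by summing weights; self-loops are dropped.  Both events are
        logged as warnings.
        """
        node_ids: list[str] = []
        index: dict[str, int] = {}
        edges: dict[tuple[int, int], float] = {}

        def idx(u: str) -> int:
            if u not in index:
                index[u] = len(node_ids)
                node_ids.append(u)
            return index[u]

        for u, v, w in edge_iter:
            if not isinstance(w, numbers.Real) or not np.isfinite(w):
                raise GraphFormatError(f"non-numeric weight {w!r} on edge {u}-{v}")
            if w < 0:
                raise GraphFormatError(f"negative weight {w} on edge {u}-{v}")
            i, j = idx(str(u)), idx(str(v))
            if i == j:
                logger.warning("%s: dropping self-loop on node %r", warn_context, u)
                continue
            key = (min(i, j), max(i, j))
            if key in edges:
                logger.warning(
                    "%s: duplicate edge %s-%s merged by summing weights", warn_context, u, v
                )
                edges[key] += float(w)
            else:
                edges[key] = float(w)
        if len(node_ids) < 2:
            raise GraphFormatError(
                f"{warn_context}: fewer than 2 nodes after parsing"
            )
        return cls(node_ids=node_ids, edges=edges)


@dataclass
class LayoutTable:
    """Per-node layout rows: id, 2-D coordinates and Gaussian width."""

    node_id: list[str]
    x: np.ndarray
    y: np.ndarray
    width: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if not (len(self.node_id) == len(self.x) == len(self.y) == len(self.width)):
            raise GraphFormatError("layout table columns have unequal lengths")
        if np.any(self.width <= 0):
            raise GraphFormatError("layout widths must be positive")

    def as_dict(self) -> dict[str, tuple[float, float, float]]:
        return {
            nid: (float(self.x[k]), float(self.y[k]), float(self.width[k]))
            for k, nid in enumerate(self.node_id)
        }


# ---------------------------------------------------------------------------
# readers


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".graphml", ".xml"}:
        return "graphml"
    if suffix == ".sif":
        return "sif"
    return "edgelist"


def _parse_weight(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise GraphFormatError(
            f"{path}:{lineno}: malformed weight {token!r}"
        ) from None


def _iter_edgelist(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                yield parts[0], parts[1], 1.0
            elif len(parts) == 3:
                yield parts[0], parts[1], _parse_weight(parts[2], path, lineno)
            else:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )


def _iter_sif(path: Path):
    # SIF lines: "source interaction target [target2 ...]"; the interaction
    # type token is ignored beyond its delimiting role.  Single-token lines
    # declare isolated nodes, which this pairwise model cannot use; skipped
    # with a warning.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 1:
                logger.warning("%s:%d: isolated node %r ignored", path, lineno, parts[0])
                continue
            if len(parts) < 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: SIF line needs source, type and >=1 target"
                )
            src = parts[0]
            for tgt in parts[2:]:
                yield src, tgt, 1.0


def _read_graphml(path: Path) -> WeightedGraph:
    g = nx.read_graphml(path)
    if g.is_directed():
        g = g.to_undirected()

    def edge_iter():
        for u, v, data in g.edges(data=True):
            yield str(u), str(v), float(data.get("weight", 1.0))

    wg = WeightedGraph.from_edges(edge_iter(), warn_context=str(path))
    return wg


def read_network(path, format: str = "auto") -> WeightedGraph:
    """Read a network file into a :class:`WeightedGraph`.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``edgelist``, ``sif``, ``graphml`` or ``auto`` (extension
        based; unknown extensions are treated as edge lists).

    Unweighted inputs receive unit weights.  Duplicate undirected edges are
    merged by summing; self-loops are dropped (both logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format == "graphml":
        return _read_graphml(path)
    if format == "sif":
        return WeightedGraph.from_edges(_iter_sif(path), warn_context=str(path))
    if format == "edgelist":
        return WeightedGraph.from_edges(_iter_edgelist(path), warn_context=str(path))
    raise GraphFormatError(f"unknown network format {format!r}")


def read_layout(path, default_width: float = DEFAULT_WIDTH) -> LayoutTable:
    """Read a node-table CSV with columns ``node_id,x,y[,width]``.

    A missing ``width`` column is filled with ``default_width``.  GraphML
    files carrying ``x``/``y``/``width`` node attributes are also accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"layout file not found: {path}")
    if path.suffix.lower() in {".graphml", ".xml"}:
        return _read_graphml_layout(path, default_width)
    try:
        df = pd.read_csv(path, dtype={"node_id": str})
    except Exception as exc:  # malformed CSV
        raise GraphFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"node_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise GraphFormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y") + (("width",) if "width" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            row = int((coerced.isna()).idxmax())
            raise GraphFormatError(
                f"{path}: malformed numeric value in column {col!r}, row {row} "
                f"(node_id={df['node_id'].iloc[row]!r})"
            )
        df[col] = coerced
    width = (
        df["width"].to_numpy(float)
        if "width" in df.columns
        else np.full(len(df), float(default_width))
    )
    return LayoutTable(
        node_id=[str(v) for v in df["node_id"]],
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        width=width,
    )


def _read_graphml_layout(path: Path, default_width: float) -> LayoutTable:
    g = nx.read_graphml(path)
    node_id, xs, ys, ws = [], [], [], []
    for node, data in g.nodes(data=True):
        if "x" not in data or "y" not in data:
            raise GraphFormatError(f"{path}: node {node!r} lacks x/y attributes")
        node_id.append(str(node))
        xs.append(float(data["x"]))
        ys.append(float(data["y"]))
        ws.append(float(data.get("width", default_width)))
    return LayoutTable(node_id=node_id, x=np.array(xs), y=np.array(ys), width=np.array(ws))


# ---------------------------------------------------------------------------
# writers


def write_layout(layout, graph: WeightedGraph, path, format: str = "csv") -> None:
    """Write a layout for ``graph`` to ``path``.

    ``layout`` may be a :class:`LayoutTable` or an optimizer
    ``LayoutState`` (anything with ``positions`` and ``widths`` arrays in
    graph node order).  CSV output has columns ``node_id,x,y,width`` in graph
    node order; GraphML output stores the same values as node attributes
    alongside the edges.
    """
    path = Path(path)
    if hasattr(layout, "positions"):
        xs = np.asarray(layout.positions)[:, 0]
        ys = np.asarray(layout.positions)[:, 1]
        ws = np.asarray(layout.widths)
        ids = list(graph.node_ids)
    else:
        table = layout.as_dict()
        missing = [nid for nid in graph.node_ids if nid not in table]
        if missing:
            raise GraphFormatError(f"layout missing nodes: {missing}")
        ids = list(graph.node_ids)
        xs = np.array([table[nid][0] for nid in ids])
        ys = np.array([table[nid][1] for nid in ids])
        ws = np.array([table[nid][2] for nid in ids])
    if len(ids) != len(xs):
        raise GraphFormatError("layout does not cover all graph nodes")

    if format == "csv":
        df = pd.DataFrame({"node_id": ids, "x": xs, "y": ys, "width": ws})
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "graphml":
        g = graph.to_networkx()
        for k, nid in enumerate(ids):
            g.nodes[nid]["x"] = float(xs[k])
            g.nodes[nid]["y"] = float(ys[k])
            g.nodes[nid]["width"] = float(ws[k])
        nx.write_graphml(g, path)
    else:
        raise GraphFormatError(f"unknown layout format {format!r}")
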