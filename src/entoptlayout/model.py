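"""Target and representation distributions over node pairs.

The network defines a *target* distribution P over unordered node pairs:
edge weights normalized to sum 1, or — with the squaring option — the
entries of W², which measure shared-neighbour (interaction-profile)
similarity and sharpen module structure.  A layout defines a
*representation* distribution Q on the same pair set from the overlap
integrals of the per-node isotropic 2-D Gaussians,

    o_ij = (2 pi (s_i^2 + s_j^2))^-1 * exp(-|r_i - r_j|^2 / (2 (s_i^2 + s_j^2)))

normalized so that Q sums to 1.  Diagonal (self) pairs enter the pair set
only in the squared mode with the diagonal kept; a node's self-overlap is
(4 pi s_i^2)^-1, the d = 0 case of the same formula.

All distributions are stored as dense symmetric n x n matrices; a pair
(i, j) is counted once, so pair sums run over the upper triangle (plus the
diagonal when self pairs are in play).  Overlaps are computed in log space
to survive widely separated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .graph_io import WeightedGraph

#: Width floor scale: sigma_min = SIGMA_MIN_REL * layout diameter.
SIGMA_MIN_REL = 1e-6
#: Absolute floor for sigma_min (degenerate zero-diameter layouts).
SIGMA_MIN_ABS = 1e-12
#: Floor applied to Q entries after normalization.
Q_FLOOR = 1e-300

LOG_2PI = np.log(2.0 * np.pi)


class DegenerateLayoutError(RuntimeError):
    """All pairwise overlaps underflowed: the layout is pathologically spread."""


@dataclass
class TargetDistribution:
    """Probability distribution P over node pairs of a network.

    ``p`` is a symmetric matrix whose upper triangle holds the unordered
    pair probabilities; the diagonal is meaningful only when
    ``include_diagonal`` is set (squared-adjacency mode with the diagonal
    kept).  ``support`` marks pairs with positive probability.
    """

    node_ids: list[str]
    p: np.ndarray
    use_square: bool = False
    ignore_square_diagonal: bool = False
    include_diagonal: bool = False

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        n = len(self.node_ids)
        if self.p.shape != (n, n):
            raise ValueError("p matrix shape does not match node count")
        if not self.include_diagonal:
            np.fill_diagonal(self.p, 0.0)
        total = self.pair_sum(self.p)
        if not np.isclose(total, 1.0, atol=1e-12, rtol=0.0):
            raise ValueError(f"target probabilities sum to {total}, not 1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def pair_sum(self, m: np.ndarray) -> float:
        """Sum a symmetric pair matrix over the pair set (each pair once)."""
        total = float(np.triu(m, k=1).sum())
        if self.include_diagonal:
            total += float(np.trace(m))
        return total

    def pair_mask(self) -> np.ndarray:
        """Boolean matrix selecting each pair exactly once (upper triangle)."""
        n = self.n_nodes
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
        if self.include_diagonal:
            mask |= np.eye(n, dtype=bool)
        return mask

    def prob(self, a: str, b: str) -> float:
        """Probability of the unordered pair (a, b); (a, a) is a self pair."""
        i = self.node_ids.index(a)
        j = self.node_ids.index(b)
        if i == j and not self.include_diagonal:
            return 0.0
        return float(self.p[i, j])

    @property
    def n_pairs(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2 + (n if self.include_diagonal else 0)


@dataclass
class LayoutState:
    """Per-node layout parameters: 2-D positions and Gaussian widths."""

    node_ids: list[str]
    positions: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        n = len(self.node_ids)
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be an (n, 2) array")
        if self.widths.shape != (n,):
            raise ValueError("widths must be an (n,) array")
        if not np.all(np.isfinite(self.positions)) or not np.all(
            np.isfinite(self.widths)
        ):
            raise ValueError("layout contains non-finite values")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def diameter(self) -> float:
        span = self.positions.max(axis=0) - self.positions.min(axis=0)
        return float(np.hypot(*span))

    def sigma_min(self) -> float:
        """Width floor: a small fraction of the layout diameter."""
        return max(SIGMA_MIN_REL * self.diameter(), SIGMA_MIN_ABS)

    def copy(self) -> "LayoutState":
        return LayoutState(
            node_ids=list(self.node_ids),
            positions=self.positions.copy(),
            widths=self.widths.copy(),
        )


@dataclass
class RepresentationDistribution:
    """Normalized Gaussian-overlap distribution Q for a layout.

    ``q`` mirrors the target's symmetric matrix convention; ``log_q`` keeps
    the exact log probabilities (no floor) for stable KL evaluation.
    """

    node_ids: list[str]
    q: np.ndarray
    log_q: np.ndarray
    include_diagonal: bool = False
    #: number of pairwise overlap evaluations performed building this Q
    n_overlap_evals: int = field(default=0, compare=False)

    def prob(self, a: str, b: str) -> float:
        i = self.node_ids.index(a)
        j = self.node_ids.index(b)
        return float(self.q[i, j])


# ---------------------------------------------------------------------------


def build_target(
    graph: WeightedGraph,
    use_square: bool = False,
    ignore_square_diagonal: bool = False,
) -> TargetDistribution:
    """Build the target distribution P from a weighted graph.

    With ``use_square`` off, P is proportional to the edge weights.  With it
    on, W (zero diagonal) is squared; (W²)_ij counts weighted 2-step paths,
    i.e. shared neighbours.  The diagonal of W² — each node's weighted
    degree mass — either becomes self-pair probability or is discarded via
    ``ignore_square_diagonal``.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges; target distribution undefined")
    w = graph.weight_matrix()
    include_diagonal = False
    if use_square:
        m = w @ w
        if ignore_square_diagonal:
            np.fill_diagonal(m, 0.0)
        else:
            include_diagonal = True
    else:
        m = w
    total = np.triu(m, k=1).sum() + (np.trace(m) if include_diagonal else 0.0)
    if total <= 0:
        raise ValueError(
            "target has zero total mass (no off-diagonal weight after squaring)"
        )
    p = m / total
    return TargetDistribution(
        node_ids=list(graph.node_ids),
        p=p,
        use_square=use_square,
        ignore_square_diagonal=ignore_square_diagonal,
        include_diagonal=include_diagonal,
    )


def gaussian_overlap(r_i, r_j, sigma_i: float, sigma_j: float) -> float:
    """Overlap integral of two isotropic 2-D Gaussians.

    Closed form of ``integral g_i(x) g_j(x) dx``:

        (2 pi (sigma_i^2 + sigma_j^2))^-1
            * exp(-|r_i - r_j|^2 / (2 (sigma_i^2 + sigma_j^2)))
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    if not (
        np.all(np.isfinite(r_i))
        and np.all(np.isfinite(r_j))
        and np.isfinite(sigma_i)
        and np.isfinite(sigma_j)
    ):
        raise ValueError("non-finite overlap inputs")
    s = sigma_i**2 + sigma_j**2
    d2 = float(np.sum((r_i - r_j) ** 2))
    return float(np.exp(-d2 / (2.0 * s)) / (2.0 * np.pi * s))


def log_overlap_matrix(layout: LayoutState) -> np.ndarray:
    """Log pairwise overlaps for all node pairs, diagonal included.

    The diagonal entries are the self-overlaps ``-log(4 pi sigma_i^2)``,
    which is the d = 0 specialization of the pair formula with
    sigma_j = sigma_i.
    """
    pos = layout.positions
    var = layout.widths**2
    s = var[:, None] + var[None, :]
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    return -LOG_2PI - np.log(s) - d2 / (2.0 * s)


def representation(
    layout: LayoutState, target: TargetDistribution
) -> RepresentationDistribution:
    """Representation distribution Q of a layout over the target's pair set."""
    if list(layout.node_ids) != list(target.node_ids):
        raise ValueError("layout and target node orders differ")
    log_o = log_overlap_matrix(layout)
    mask = target.pair_mask()
    log_z = logsumexp(log_o[mask])
    if not np.isfinite(log_z):
        raise DegenerateLayoutError(
            "all pairwise overlaps underflowed; the layout is degenerate"
        )
    log_q = log_o - log_z
    if not target.include_diagonal:
        np.fill_diagonal(log_q, -np.inf)
    with np.errstate(under="ignore"):
        q = np.exp(log_q)
    q = np.maximum(q, Q_FLOOR)
    if not target.include_diagonal:
        np.fill_diagonal(q, 0.0)
    return RepresentationDistribution(
        node_ids=list(layout.node_ids),
        q=q,
        log_q=log_q,
        include_diagonal=target.include_diagonal,
        n_overlap_evals=target.n_pairs,
    )
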