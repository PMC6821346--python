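"""Alternating position/width minimization of the information loss.

The default schedule follows the recommended practice for this method:
five consecutive phases optimizing node position, node width, node
position, node width and node position ("PWPWP"), each phase run until the
loss change falls below a relative tolerance or an iteration cap is hit.
Each phase is full-batch gradient descent with Armijo backtracking line
search on the phase's variables only, so every accepted step strictly
decreases the loss and the loss trace is monotone within a phase.

Initialization is either seeded-random (unit square) or user-provided
coordinates; pre-ordering with a force-directed layout is supported through
the provided mode and a bundled Fruchterman-Reingold helper.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import networkx as nx
import numpy as np

from .graph_io import LayoutTable, WeightedGraph
from .model import (
    LayoutState,
    TargetDistribution,
    build_target,
    representation,
)
from .objective import LossReport, gradients, make_report, normalized_loss, relative_entropy

logger = logging.getLogger(__name__)

POSITION_PHASE = "position"
WIDTH_PHASE = "width"

#: Armijo sufficient-decrease constant.
_ARMIJO_C = 1e-4
#: Maximum backtracking halvings per step before the phase gives up.
_MAX_BACKTRACK = 60


@dataclass
class OptimizationConfig:
    """Knobs of the alternating optimizer.

    ``schedule`` is a sequence over {"position", "width"} (string shorthand
    like "PWPWP" is accepted by :func:`parse_schedule`).  ``initial_width``
    is the Gaussian standard deviation assigned at initialization, in layout
    units (the unit square for random starts).
    """

    schedule: tuple[str, ...] = (
        POSITION_PHASE,
        WIDTH_PHASE,
        POSITION_PHASE,
        WIDTH_PHASE,
        POSITION_PHASE,
    )
    max_iter_per_phase: int = 500
    rel_tol: float = 1e-9
    seed: int = 0
    init_mode: str = "random"  # "random" | "provided"
    initial_width: float = 0.1
    use_square: bool = False
    ignore_square_diagonal: bool = False
    report_every: int = 10
    time_limit: Optional[float] = None  # seconds, advisory, checked between iterations
    restarts: int = 0

    def __post_init__(self):
        if len(self.schedule) == 0:
            raise ValueError("schedule must be non-empty")
        for ph in self.schedule:
            if ph not in (POSITION_PHASE, WIDTH_PHASE):
                raise ValueError(f"unknown phase {ph!r}")
        if self.max_iter_per_phase < 1:
            raise ValueError("max_iter_per_phase must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.initial_width <= 0:
            raise ValueError("initial_width must be positive")


def parse_schedule(text: str) -> tuple[str, ...]:
    """Parse a schedule string of P/W characters, e.g. ``"PWPWP"``."""
    mapping = {"P": POSITION_PHASE, "W": WIDTH_PHASE}
    try:
        return tuple(mapping[c] for c in text.upper())
    except KeyError as exc:
        raise ValueError(f"schedule may only contain P and W, got {text!r}") from exc


# ---------------------------------------------------------------------------
# initialization


def initialize(
    graph: WeightedGraph,
    config: OptimizationConfig,
    provided: Optional[LayoutTable] = None,
) -> LayoutState:
    """Initial layout: seeded-random in the unit square, or user coordinates.

    Coincident nodes are separated by a tiny seeded jitter (1e-6 of a layout
    unit) so that symmetric zero-distance configurations cannot lock the
    gradient flow.
    """
    rng = np.random.default_rng(config.seed)
    n = graph.n_nodes
    if provided is not None:
        table = provided.as_dict()
        missing = [nid for nid in graph.node_ids if nid not in table]
        if missing:
            raise ValueError(f"provided layout missing nodes: {missing}")
        pos = np.array([[table[nid][0], table[nid][1]] for nid in graph.node_ids])
        widths = np.array([table[nid][2] for nid in graph.node_ids])
    elif config.init_mode == "provided":
        raise ValueError("init_mode='provided' but no layout given")
    else:
        pos = rng.random((n, 2))
        widths = np.full(n, config.initial_width)

    # de-duplicate coincident positions with seeded jitter
    _, inverse, counts = np.unique(
        pos, axis=0, return_inverse=True, return_counts=True
    )
    dup = counts[inverse] > 1
    if np.any(dup):
        pos = pos.copy()
        pos[dup] += rng.normal(scale=1e-6, size=(int(dup.sum()), 2))
    return LayoutState(node_ids=list(graph.node_ids), positions=pos, widths=widths)


def force_directed_layout(
    graph: WeightedGraph, seed: int = 0, initial_width: float = 0.1
) -> LayoutTable:
    """Fruchterman-Reingold baseline coordinates (conventional layout).

    A spring-embedder of the kind this method is benchmarked against; also
    useful as a pre-ordering before entropy optimization.
    """
    g = graph.to_networkx()
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    ids = list(graph.node_ids)
    xy = np.array([pos[nid] for nid in ids])
    return LayoutTable(
        node_id=ids,
        x=xy[:, 0],
        y=xy[:, 1],
        width=np.full(len(ids), initial_width),
    )


# ---------------------------------------------------------------------------
# phase optimization


def _loss(layout: LayoutState, target: TargetDistribution) -> float:
    return relative_entropy(target, representation(layout, target))


def run_phase(
    layout: LayoutState,
    target: TargetDistribution,
    phase: str,
    config: OptimizationConfig,
    phase_label: Optional[str] = None,
    callback: Optional[Callable[[str, int, float], None]] = None,
    deadline: Optional[float] = None,
) -> tuple[LayoutState, LossReport]:
    """Minimize the loss over one variable block (positions XOR widths).

    Gradient descent with backtracking line search; only strictly
    loss-decreasing steps are accepted, so the returned report's trace is
    non-increasing.  Widths are clamped at the sigma_min floor.  Stops at
    ``max_iter_per_phase`` iterations, at relative loss change below
    ``rel_tol``, or when no decreasing step can be found.
    """
    if phase not in (POSITION_PHASE, WIDTH_PHASE):
        raise ValueError(f"unknown phase {phase!r}")
    label = phase_label or phase
    layout = layout.copy()

    f = _loss(layout, target)
    if not np.isfinite(f):
        raise FloatingPointError(f"non-finite loss at phase start ({label})")
    nloss = normalized_loss(f, target)
    trace: list[tuple[str, int, float]] = [(label, 0, nloss)]
    if callback:
        callback(label, 0, nloss)

    step = 1.0
    prev_x = None
    prev_g = None
    for it in range(1, config.max_iter_per_phase + 1):
        if deadline is not None and time.monotonic() > deadline:
            logger.info("%s: time limit reached at iteration %d", label, it)
            break
        pos_grad, width_grad = gradients(layout, target)
        if phase == POSITION_PHASE:
            g = pos_grad
            x = layout.positions
        else:
            g = width_grad
            x = layout.widths
            # project the gradient at the active width floor
            floor = layout.sigma_min()
            at_floor = layout.widths <= floor
            g = np.where(at_floor & (g > 0), 0.0, g)
        gnorm2 = float(np.sum(g * g))
        if gnorm2 == 0.0:
            break

        # Barzilai-Borwein initial step (spectral step length); Armijo
        # backtracking below keeps every accepted step a strict decrease
        if prev_x is not None:
            s = x - prev_x
            y = g - prev_g
            sy = float(np.sum(s * y))
            if sy > 0:
                step = float(np.sum(s * s)) / sy
        prev_x, prev_g = x.copy(), g.copy()

        accepted = False
        alpha = step
        for _ in range(_MAX_BACKTRACK):
            trial = layout.copy()
            if phase == POSITION_PHASE:
                trial.positions = layout.positions - alpha * g
            else:
                new_w = layout.widths - alpha * g
                trial.widths = np.maximum(new_w, layout.sigma_min())
            try:
                f_trial = _loss(trial, target)
            except FloatingPointError:
                f_trial = np.inf
            if np.isfinite(f_trial) and f_trial <= f - _ARMIJO_C * alpha * gnorm2:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break

        rel_change = (f - f_trial) / max(abs(f), 1e-300)
        layout, f = trial, f_trial
        step = alpha * 2.0  # warm-start the next line search
        nloss = normalized_loss(f, target)
        if it % config.report_every == 0 or it == config.max_iter_per_phase:
            trace.append((label, it, nloss))
            if callback:
                callback(label, it, nloss)
        if rel_change < config.rel_tol:
            break
    if trace[-1][1] != it or trace[-1][2] != nloss:
        trace.append((label, it, nloss))

    report = make_report(target, representation(layout, target))
    report.trace = trace
    return layout, report


# ---------------------------------------------------------------------------
# full optimization


def optimize(
    graph: WeightedGraph,
    config: Optional[OptimizationConfig] = None,
    provided: Optional[LayoutTable] = None,
    callback: Optional[Callable[[str, int, float], None]] = None,
) -> tuple[LayoutState, LossReport]:
    """Run the full alternating schedule and return (layout, report).

    Builds the target per the config's squaring flags, initializes (random
    or provided), and executes each scheduled phase in turn.  The report
    concatenates every phase's trace with labels like ``P1, W2, P3, ...``.
    Deterministic given the config seed and inputs.  With ``restarts > 0``
    the whole run is repeated with derived seeds and the lowest-loss result
    is returned.
    """
    config = config or OptimizationConfig()
    if config.restarts > 0:
        best: Optional[tuple[LayoutState, LossReport]] = None
        for k in range(config.restarts + 1):
            sub = replace(config, restarts=0, seed=(config.seed + 9973 * k) % 2**31)
            result = optimize(graph, sub, provided=provided, callback=callback)
            if best is None or result[1].normalized_loss < best[1].normalized_loss:
                best = result
        return best

    target = build_target(
        graph,
        use_square=config.use_square,
        ignore_square_diagonal=config.ignore_square_diagonal,
    )
    layout = initialize(graph, config, provided=provided)
    deadline = (
        time.monotonic() + config.time_limit if config.time_limit is not None else None
    )
    full_trace: list[tuple[str, int, float]] = []
    report = None
    for k, phase in enumerate(config.schedule, start=1):
        label = ("P" if phase == POSITION_PHASE else "W") + str(k)
        layout, report = run_phase(
            layout,
            target,
            phase,
            config,
            phase_label=label,
            callback=callback,
            deadline=deadline,
        )
        full_trace.extend(report.trace)
    report.trace = full_trace
    return layout, report
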