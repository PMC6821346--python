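"""Scoring fixed layouts and comparing layout methods.

A foreign layout (produced by any tool) is scored by the width-only
protocol: its node positions are frozen and only the node Gaussians'
widths are optimized, and the resulting normalized information loss is the
layout's D.  This makes scores of different layout algorithms directly
comparable on the same network.  Fold improvement between two layouts is
the ratio of their D values; module separation is an auxiliary silhouette
diagnostic of how spatially distinct known modules are.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .graph_io import LayoutTable, WeightedGraph
from .model import LayoutState, build_target
from .objective import LossReport
from .optimizer import (
    WIDTH_PHASE,
    OptimizationConfig,
    initialize,
    run_phase,
)


def score_external_layout(
    graph: WeightedGraph,
    positions: LayoutTable,
    use_square: bool = False,
    ignore_square_diagonal: bool = False,
    config: Optional[OptimizationConfig] = None,
) -> LossReport:
    """Normalized information loss of a fixed layout.

    Node positions come from ``positions`` and stay frozen; widths start
    from the layout table's width column (the configured default when the
    file had none) and are optimized to convergence.  Deterministic: the
    width phase uses no randomness.
    """
    config = config or OptimizationConfig()
    cfg = replace(
        config,
        init_mode="provided",
        use_square=use_square,
        ignore_square_diagonal=ignore_square_diagonal,
    )
    target = build_target(
        graph, use_square=use_square, ignore_square_diagonal=ignore_square_diagonal
    )
    layout = initialize(graph, cfg, provided=positions)
    _, report = run_phase(layout, target, WIDTH_PHASE, cfg, phase_label="W(score)")
    return report


def fold_improvement(d_baseline: float, d_entopt: float) -> float:
    """Ratio of a baseline layout's loss to the entropy-optimized loss.

    Both losses must come from the same graph and squaring flags (the
    entropy normalizer then cancels, so raw and normalized losses give the
    same ratio).  A zero optimized loss yields ``inf`` — a flagged perfect
    representation, not an error.
    """
    if d_baseline < 0 or d_entopt < 0:
        raise ValueError("losses must be non-negative")
    if d_entopt == 0.0:
        return math.inf
    return d_baseline / d_entopt


def module_separation(layout: LayoutState, labels: Sequence) -> float:
    """Mean silhouette of node positions under the given module labels.

    Range [-1, 1]; higher means modules occupy more distinct regions.
    Degenerate inputs (all positions identical) score 0 by convention, as
    do singleton modules (their members contribute 0).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != layout.n_nodes:
        raise ValueError("one label per node required")
    if len(np.unique(labels)) < 2:
        raise ValueError("module_separation needs >= 2 distinct labels")
    pos = layout.positions
    if np.allclose(pos, pos[0], atol=0.0):
        return 0.0
    # silhouette_score rejects singleton-free degenerate cases itself;
    # sklearn already assigns 0 to singleton clusters (its convention too)
    return float(silhouette_score(pos, labels, metric="euclidean"))


def compare_layouts(
    graph: WeightedGraph,
    layouts: dict[str, LayoutTable],
    use_square: bool = False,
    ignore_square_diagonal: bool = False,
    config: Optional[OptimizationConfig] = None,
) -> pd.DataFrame:
    """Score several named layouts on one network.

    Returns a table with columns ``layout_name, kl, target_entropy,
    normalized_loss, fold_vs_best`` where ``fold_vs_best`` is each layout's
    loss divided by the smallest loss in the table (1.0 for the winner).
    """
    if len(layouts) < 2:
        raise ValueError("need at least 2 layouts to compare")
    rows = []
    for name, table in layouts.items():
        rep = score_external_layout(
            graph,
            table,
            use_square=use_square,
            ignore_square_diagonal=ignore_square_diagonal,
            config=config,
        )
        rows.append(
            {
                "layout_name": name,
                "kl": rep.kl,
                "target_entropy": rep.target_entropy,
                "normalized_loss": rep.normalized_loss,
            }
        )
    df = pd.DataFrame(rows)
    best = df["normalized_loss"].min()
    if best > 0:
        df["fold_vs_best"] = df["normalized_loss"] / best
    else:
        df["fold_vs_best"] = np.where(df["normalized_loss"] == 0, 1.0, np.inf)
    return df
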