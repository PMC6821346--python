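"""The information-loss objective and its analytic gradients.

The layout quality score is the relative entropy (Kullback-Leibler
divergence) between the network's pair distribution P and the layout's
Gaussian-overlap distribution Q,

    D(P || Q) = sum_{pairs, p > 0} p * ln(p / q)     [nats]

reported normalized by the target entropy H(P) = -sum p ln p, so that the
score is dimensionless and comparable across networks of different size.
Fold ratios between layouts of the same network are unaffected by the
normalization.

Writing o_k for the raw overlap of pair k and Z = sum_k o_k, we have
ln q_k = ln o_k - ln Z and hence for any layout parameter theta

    dD/dtheta = sum_k (q_k - p_k) * d ln o_k / dtheta ,

the Z term contributing the q_k weight.  With
ln o_ij = -ln(2 pi) - ln s_ij - d_ij^2 / (2 s_ij), s_ij = s_i^2 + s_j^2:

    d ln o_ij / d r_i     = -(r_i - r_j) / s_ij
    d ln o_ij / d sigma_i = 2 sigma_i * (d_ij^2 / (2 s_ij^2) - 1 / s_ij)

and for a self pair, d ln o_ii / d sigma_i = -2 / sigma_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import LayoutState, RepresentationDistribution, TargetDistribution


@dataclass
class LossReport:
    """Result of a loss evaluation or an optimization run.

    ``trace`` records ``(phase_label, iteration, normalized_loss)`` tuples;
    within each phase the recorded values are non-increasing because only
    loss-decreasing steps are accepted.
    """

    kl: float
    target_entropy: float
    normalized_loss: float
    trace: list[tuple[str, int, float]] = field(default_factory=list)
    #: True when H(P) = 0, in which case normalized_loss is the raw KL.
    degenerate_normalizer: bool = False

    def to_dict(self) -> dict:
        return {
            "kl": self.kl,
            "target_entropy": self.target_entropy,
            "normalized_loss": self.normalized_loss,
            "degenerate_normalizer": self.degenerate_normalizer,
            "trace": [list(t) for t in self.trace],
        }


def relative_entropy(
    target: TargetDistribution, rep: RepresentationDistribution
) -> float:
    """D(P || Q) in nats over the common pair set.

    Pairs with p = 0 contribute exactly zero.  Q is strictly positive by
    construction; a zero q on the support signals corrupted input.
    """
    if list(target.node_ids) != list(rep.node_ids):
        raise ValueError("target and representation node orders differ")
    mask = target.pair_mask() & (target.p > 0)
    p = target.p[mask]
    log_q = rep.log_q[mask]
    if np.any(~np.isfinite(log_q)):
        raise ValueError("q = 0 on the target support; corrupted representation")
    kl = float(np.sum(p * (np.log(p) - log_q)))
    # rounding can push an exact-representation KL a few ulp below zero
    return 0.0 if -1e-12 < kl < 0.0 else kl


def target_entropy(target: TargetDistribution) -> float:
    """Shannon entropy H(P) = -sum_{p>0} p ln p, in nats."""
    mask = target.pair_mask() & (target.p > 0)
    p = target.p[mask]
    return float(-np.sum(p * np.log(p)))


def normalized_loss(kl: float, target: TargetDistribution) -> float:
    """KL divided by H(P); the raw KL when H(P) = 0 (single-pair targets)."""
    h = target_entropy(target)
    if h > 0:
        return kl / h
    return kl


def make_report(
    target: TargetDistribution, rep: RepresentationDistribution
) -> LossReport:
    """Bundle KL, entropy and normalized loss for one evaluation."""
    kl = relative_entropy(target, rep)
    h = target_entropy(target)
    return LossReport(
        kl=kl,
        target_entropy=h,
        normalized_loss=kl / h if h > 0 else kl,
        degenerate_normalizer=(h == 0.0),
    )


def gradients(
    layout: LayoutState, target: TargetDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of D(P || Q(layout)) w.r.t. positions and widths.

    Returns ``(pos_grad, width_grad)`` with shapes (n, 2) and (n,).  The
    normalization of Q couples every pair; the (q - p) weight accounts for
    it exactly (see module docstring).
    """
    from .model import representation

    rep = representation(layout, target)
    n = layout.n_nodes
    pos = layout.positions
    sig = layout.widths
    var = sig**2
    s = var[:, None] + var[None, :]
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    a = rep.q - target.p  # symmetric (q - p) over pairs
    np.fill_diagonal(a, 0.0)  # off-diagonal terms first

    # position gradient: -sum_j a_ij (r_i - r_j) / s_ij
    coef = a / s
    pos_grad = -np.einsum("ij,ijk->ik", coef, diff)

    # width gradient, off-diagonal part:
    #   sum_j a_ij * 2 sigma_i * (d_ij^2 / (2 s_ij^2) - 1 / s_ij)
    dlnods = d2 / (2.0 * s**2) - 1.0 / s
    width_grad = 2.0 * sig * np.einsum("ij,ij->i", a, dlnods)

    if target.include_diagonal:
        # self pairs: d ln o_ii / d sigma_i = -2 / sigma_i
        a_diag = np.diag(rep.q) - np.diag(target.p)
        width_grad += a_diag * (-2.0 / sig)

    return pos_grad, width_grad
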