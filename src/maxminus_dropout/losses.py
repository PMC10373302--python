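"""Training objective: dual-pass cross-entropy, bidirectional KL consistency,
and the negative-distribution regularizer.

For an input x fed twice through the dropout network (distributions P1, P2)
and a negative sample x_ng fed once (P_ng), one step optimizes

    L = L_CE + alpha * (L_KL - L_NG)

where L_CE = mean_i [-log P1[i, y_i] - log P2[i, y_i]] pulls both passes to
the label, L_KL = mean_i 1/2 [KL(P1_i || P2_i) + KL(P2_i || P1_i)] keeps the
dropout sub-models consistent with each other, and the subtracted
L_NG = mean_ij (1/2 (P1 + P2) - P_ng)_{ij}^2 pushes the negative sample's
distribution away from the positive mean.  L_NG is bounded by 1 on the
probability simplex, so -alpha * L_NG cannot diverge.  All logarithms are
natural and floored at eps = 1e-12.

Every function here accepts plain ``numpy`` arrays or autodiff
:class:`~maxminus_dropout.autodiff.Tensor` objects, so the same code path
is used for reporting and for gradient computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

EPS = 1e-12


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _floor(p, eps: float = EPS):
    return p.clip_min(eps) if _is_tensor(p) else np.maximum(p, eps)


def _log(p):
    return p.log() if _is_tensor(p) else np.log(p)


def _shape(p):
    return p.shape


def _check_probs(name: str, p) -> None:
    data = p.data if _is_tensor(p) else np.asarray(p)
    if data.ndim != 2:
        raise ValueError(f"{name} must be 2-D (batch x classes), got {data.shape}")
    if (data < -1e-9).any() or (data > 1 + 1e-9).any():
        raise ValueError(f"{name} entries must lie in [0, 1]")
    rowsums = data.sum(axis=1)
    if np.abs(rowsums - 1.0).max() > 1e-6:
        raise ValueError(f"{name} rows must sum to 1 (max deviation "
                         f"{np.abs(rowsums - 1.0).max():.2e})")


@dataclass(frozen=True)
class PredictionTriplet:
    """The three per-batch output distributions of one training step."""

    p1: np.ndarray
    p2: np.ndarray
    p_ng: np.ndarray

    def __post_init__(self):
        for name in ("p1", "p2", "p_ng"):
            arr = getattr(self, name)
            if not _is_tensor(arr):
                object.__setattr__(self, name, np.asarray(arr, dtype=np.float64))
            _check_probs(name, getattr(self, name))
        if _shape(self.p1) != _shape(self.p2) or _shape(self.p1) != _shape(self.p_ng):
            raise ValueError("P1, P2 and P_ng must share one shape")


@dataclass(frozen=True)
class LossBreakdown:
    """Loss components (nats) and their combination for one step."""

    l_ce: float
    l_kl: float
    l_ng: float
    alpha: float
    total: float

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        expected = self.l_ce + self.alpha * (self.l_kl - self.l_ng)
        if abs(self.total - expected) > 1e-9:
            raise ValueError(f"total {self.total} inconsistent with components "
                             f"(expected {expected})")


def bidirectional_kl(p1, p2):
    """Mean over the batch of 1/2 [KL(P1 || P2) + KL(P2 || P1)], in nats."""
    if _shape(p1) != _shape(p2):
        raise ValueError(f"shape mismatch: {_shape(p1)} vs {_shape(p2)}")
    lp1, lp2 = _log(_floor(p1)), _log(_floor(p2))
    fwd = (p1 * (lp1 - lp2)).sum(axis=1)
    bwd = (p2 * (lp2 - lp1)).sum(axis=1)
    return (0.5 * (fwd + bwd)).mean()


def dual_cross_entropy(p1, p2, y):
    """Mean over the batch of -log P1[i, y_i] - log P2[i, y_i], in nats."""
    if _shape(p1) != _shape(p2):
        raise ValueError(f"shape mismatch: {_shape(p1)} vs {_shape(p2)}")
    y = np.asarray(y)
    n, k = _shape(p1)
    if y.shape != (n,):
        raise ValueError("y must hold one class index per row")
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"label indices must lie in [0, {k})")
    rows = np.arange(n)
    t1 = _log(_floor(p1)[rows, y])
    t2 = _log(_floor(p2)[rows, y])
    return (-(t1 + t2)).mean()


def negative_mse(p1, p2, p_ng):
    """Mean squared gap between the positive mean 1/2 (P1+P2) and P_ng.

    Averaged over batch and classes, so the value lies in [0, 1] for rows
    on the probability simplex.  This term is *subtracted* in the total
    objective: training pushes it up.
    """
    for other in (p2, p_ng):
        if _shape(p1) != _shape(other):
            raise ValueError(f"shape mismatch: {_shape(p1)} vs {_shape(other)}")
    m = 0.5 * (p1 + p2)
    return ((m - p_ng) ** 2).mean()


def negative_kl(p1, p2, p_ng):
    """Ablation variant: bidirectional KL between the positive mean and P_ng."""
    return bidirectional_kl(0.5 * (p1 + p2), p_ng)


def total_loss(ce, kl, ng, alpha: float) -> LossBreakdown:
    """Combine components into L = L_CE + alpha * (L_KL - L_NG)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    ce, kl, ng = float(ce), float(kl), float(ng)
    return LossBreakdown(l_ce=ce, l_kl=kl, l_ng=ng, alpha=float(alpha),
                         total=ce + alpha * (kl - ng))
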