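"""Focal loss and the multi-level total loss.

Each taxonomy level is a multi-label task: the model emits one sigmoid
probability per class and every (sample, class) cell is a binary problem.
Because the class counts are heavily imbalanced, each cell is scored with the
focal loss

    FL(p_t) = -(1 - p_t)^gamma * log(p_t),   p_t = p if y = 1 else 1 - p,

which is plain binary cross-entropy modulated by ``(1 - p_t)^gamma`` so that
easy, well-classified cells contribute little and training concentrates on
hard examples.  ``gamma = 0`` recovers cross-entropy exactly.

The per-level losses are combined into the total training objective as a
convex combination

    Loss_T = w_1 * loss_1 + ... + w_L * loss_L,

which for two levels reads ``alpha * loss_l1 + (1 - alpha) * loss_l2`` with
``alpha`` constrained to (0, 0.5): the finer level carries more weight because
fine-grained identification is the end goal.  ``alpha = 0.3`` (a 3:7 ratio)
is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FocalParams",
    "LevelWeights",
    "focal_term",
    "focal_grad",
    "level_loss",
    "level_loss_grad",
    "total_loss",
    "EPSILON",
]

#: probabilities are clamped to [EPSILON, 1 - EPSILON] before taking logs
EPSILON = 1e-7


@dataclass(frozen=True)
class FocalParams:
    """Focal-loss hyperparameters.

    gamma : focusing parameter, >= 0.  0 = cross-entropy; 2 is the canonical
        default of the focal-loss literature.
    epsilon : probability clamp bound guarding log(0).
    """

    gamma: float = 2.0
    epsilon: float = EPSILON

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")


@dataclass(frozen=True)
class LevelWeights:
    """Convex per-level loss weights w_1..w_L.

    For the two-level case use :meth:`from_alpha`; the level-1 weight alpha is
    restricted to (0, 0.5) so the finer level always dominates.
    """

    weights: tuple[float, ...] = field(default=(0.3, 0.7))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D sequence")
        if (w < 0).any() or (w > 1).any():
            raise ValueError("weights must lie in [0, 1]")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if w.size == 2 and not (0.0 < w[0] < 0.5):
            raise ValueError(
                f"for two levels the level-1 weight must lie in (0, 0.5), got {w[0]}"
            )

    @classmethod
    def from_alpha(cls, alpha: float) -> "LevelWeights":
        return cls((float(alpha), 1.0 - float(alpha)))

    @property
    def alpha(self) -> float:
        return self.weights[0]


def _clamp(p: np.ndarray, epsilon: float) -> np.ndarray:
    return np.clip(p, epsilon, 1.0 - epsilon)


def focal_term(p, y, gamma: float = 2.0, epsilon: float = EPSILON):
    """Focal loss of a single binary cell (vectorized over arrays).

    Parameters
    ----------
    p : probability assigned to class 1, in [0, 1]
    y : ground-truth label in {0, 1}
    gamma : focusing parameter >= 0

    Returns ``(1 - p_t)**gamma * (-log p_t)`` with ``p_t = p`` when ``y = 1``
    and ``1 - p`` otherwise, after clamping p away from {0, 1}.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    pc = _clamp(p, epsilon)
    pt = np.where(y == 1, pc, 1.0 - pc)
    out = (1.0 - pt) ** gamma * (-np.log(pt))
    return out if out.ndim else float(out)


def focal_grad(p, y, gamma: float = 2.0, epsilon: float = EPSILON):
    """Analytic d focal_term / d p (zero where p is clamped)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    pc = _clamp(p, epsilon)
    pt = np.where(y == 1, pc, 1.0 - pc)
    one_minus = 1.0 - pt
    # d/dpt [ (1-pt)^g * (-ln pt) ] = -g (1-pt)^(g-1) (-ln pt) - (1-pt)^g / pt
    if gamma == 0:
        dpt = -1.0 / pt
    else:
        dpt = -gamma * one_minus ** (gamma - 1.0) * (-np.log(pt)) - one_minus**gamma / pt
    dp = np.where(y == 1, dpt, -dpt)
    inside = (p > epsilon) & (p < 1.0 - epsilon)
    out = np.where(inside, dp, 0.0)
    return out if out.ndim else float(out)


def level_loss(scores, labels, params: FocalParams = FocalParams()) -> float:
    """Mean focal loss over all (sample, class) cells of one taxonomy level.

    ``scores`` are post-sigmoid probabilities, shape (n_samples, n_classes);
    ``labels`` is the matching multi-hot matrix.  Mean reduction keeps the
    level-weight alpha's meaning independent of how many classes a level has.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(labels)
    if s.shape != t.shape:
        raise ValueError(f"scores shape {s.shape} != labels shape {t.shape}")
    if s.size == 0:
        raise ValueError("empty batch")
    return float(np.mean(focal_term(s, t, params.gamma, params.epsilon)))


def level_loss_grad(scores, labels, params: FocalParams = FocalParams()) -> np.ndarray:
    """Analytic gradient of :func:`level_loss` w.r.t. the score matrix."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(labels)
    return np.asarray(focal_grad(s, t, params.gamma, params.epsilon)) / s.size


def total_loss(level_losses: Sequence[float], weights: LevelWeights) -> float:
    """Weighted total loss  sum_l w_l * loss_l  across taxonomy levels."""
    losses = np.asarray(level_losses, dtype=float)
    w = np.asarray(weights.weights, dtype=float)
    if losses.shape != w.shape:
        raise ValueError(
            f"{losses.size} level losses but {w.size} weights"
        )
    return float(np.dot(w, losses))
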