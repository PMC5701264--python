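"""Exponentially weighted running moments and batch standardization.

Each tensor coordinate is tracked independently through three
accumulators: the effective observation count ``n_eff``, the weighted sum
``S`` and the weighted sum of squares ``SS``.  With forgetting factor
``λ`` the update on a batch of ``N_t`` epochs is::

    n_eff ← λ·n_eff + N_t
    S     ← λ·S     + Σ_l x_l
    SS    ← λ·SS    + Σ_l x_l²

from which the effective mean is ``S / n_eff`` and the effective standard
deviation ``sqrt((SS − S²/n_eff) / (n_eff − 1))``.  At ``λ = 1`` these are
exactly the pooled sample mean and (ddof=1) standard deviation of all
epochs seen; at ``λ < 1`` they are the λ^age-weighted analogues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RunningMoments", "update_moments", "mean_std", "standardize", "destandardize"]

logger = logging.getLogger(__name__)

#: variance floor used when dividing by a standard deviation
DEFAULT_EPS = 1e-12


@dataclass(frozen=True)
class RunningMoments:
    """Immutable snapshot of the exponentially weighted moment accumulators."""

    shape: tuple[int, ...]
    lam: float
    n_eff: float = 0.0
    sum: np.ndarray | None = None
    sum_sq: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"forgetting factor must lie in [0, 1], got {self.lam}")
        if self.sum is None:
            object.__setattr__(self, "sum", np.zeros(self.shape))
        if self.sum_sq is None:
            object.__setattr__(self, "sum_sq", np.zeros(self.shape))


def update_moments(state: RunningMoments, batch: np.ndarray) -> RunningMoments:
    """Fold one batch (observations on the first axis) into the moments.

    Returns a new state; the input state is unmodified.  An empty batch
    only decays ``n_eff`` (and the sums) by ``λ``.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.shape[0] == 0:
        logger.info("empty batch: decaying moments by lambda=%g only", state.lam)
        return replace(
            state,
            n_eff=state.lam * state.n_eff,
            sum=state.lam * state.sum,
            sum_sq=state.lam * state.sum_sq,
        )
    if tuple(batch.shape[1:]) != tuple(state.shape):
        raise ValueError(
            f"batch coordinate shape {batch.shape[1:]} != state shape {state.shape}"
        )
    if not np.all(np.isfinite(batch)):
        raise ValueError("batch contains non-finite values")
    lam = state.lam
    return replace(
        state,
        n_eff=lam * state.n_eff + batch.shape[0],
        sum=lam * state.sum + batch.sum(axis=0),
        sum_sq=lam * state.sum_sq + np.square(batch).sum(axis=0),
    )


def mean_std(state: RunningMoments) -> tuple[np.ndarray, np.ndarray]:
    """Effective mean and standard deviation of the tracked stream.

    Requires ``n_eff > 1`` (the variance uses an ``n_eff − 1``
    denominator).  Negative variances arising from rounding on constant
    coordinates are clipped to zero.
    """
    if state.n_eff <= 1.0:
        raise ValueError(
            f"variance undefined: effective observation count {state.n_eff} <= 1"
        )
    mean = state.sum / state.n_eff
    var = (state.sum_sq - np.square(state.sum) / state.n_eff) / (state.n_eff - 1.0)
    std = np.sqrt(np.maximum(var, 0.0))
    return mean, std


def standardize(
    batch: np.ndarray,
    mean: np.ndarray,
    std: np.ndarray,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Center and rescale each coordinate: ``(batch − mean) / max(std, eps)``."""
    return (np.asarray(batch, dtype=float) - mean) / np.maximum(std, eps)


def destandardize(
    batch: np.ndarray,
    mean: np.ndarray,
    std: np.ndarray,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Inverse of :func:`standardize` (with the same ``eps`` guard)."""
    return np.asarray(batch, dtype=float) * np.maximum(std, eps) + mean
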