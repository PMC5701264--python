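"""Modality-influence analysis of a coefficient tensor.

The influence of one modality (frequency, temporal bin, channel, …) on a
fitted multilinear model is the profile of summed absolute coefficients
along that mode, normalized to unit total weight.  For a rank-one
coefficient tensor the profile over mode k is exactly the normalized
|w^k| of that mode's projector, so the profiles read out which
frequencies, lags and electrodes drive the decoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["InfluenceProfile", "modality_influence"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InfluenceProfile:
    """Nonnegative unit-sum weights of one modality."""

    modality: int
    weights: np.ndarray
    degenerate: bool = False  # all-zero model: uniform fallback profile

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)


def modality_influence(b: np.ndarray, modality: int) -> InfluenceProfile:
    """Weight profile of ``modality`` in the coefficient tensor ``b``.

    ``weights[i] ∝ Σ |b[..., i, ...]|`` over all other indices (input and
    output modes alike), normalized to sum to one.  Scale-invariant:
    ``cB`` gives the same profile for any ``c ≠ 0``.  An all-zero tensor
    yields the uniform profile, flagged ``degenerate``.
    """
    b = np.asarray(b, dtype=float)
    if not -b.ndim <= modality < b.ndim:
        raise IndexError(f"mode {modality} invalid for an order-{b.ndim} tensor")
    modality = modality % b.ndim
    other = tuple(k for k in range(b.ndim) if k != modality)
    raw = np.abs(b).sum(axis=other)
    total = raw.sum()
    if total == 0.0:
        logger.warning("all-zero coefficient tensor: uniform influence profile")
        size = b.shape[modality]
        return InfluenceProfile(modality, np.full(size, 1.0 / size), degenerate=True)
    return InfluenceProfile(modality, raw / total)
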