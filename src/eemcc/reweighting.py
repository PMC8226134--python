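"""Frame weights from a saved metadynamics bias and weighted estimators.

A well-tempered metadynamics run samples exp(-(U + V)/kBT); removing
the bias to recover Boltzmann statistics weights each frame by

    w(t) = exp(+V(s, t) / kB T)

using the history-dependent bias value saved at the frame's time.
Weights are rescaled by a common factor (the maximum bias) for
numerical range, which leaves every weighted average unchanged.  By
convention the weights apply to water/excipient statistics, energies
and contact tables, but not to protein entropy terms, whose
conformations are not driven by the bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants


@dataclass
class FrameWeights:
    """Positive per-frame weights; a constant bias gives equal weights."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(~np.isfinite(self.w)) or np.any(self.w <= 0):
            raise ValueError("frame weights must be finite and positive")

    def __len__(self) -> int:
        return len(self.w)


def frame_weights(
    bias: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    sign: int = +1,
) -> FrameWeights:
    """Unbiasing weights from per-frame bias values (kJ mol^-1).

    ``sign=+1`` (default) gives the statistically correct unbiasing
    factor exp(+V/kBT); ``sign=-1`` is available for bias files whose
    sign convention is already inverted.
    """
    bias = np.asarray(bias, dtype=float)
    if np.any(~np.isfinite(bias)):
        raise ValueError("non-finite bias value")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    v = sign * bias / constants.kBT_kj_mol
    return FrameWeights(w=np.exp(v - v.max()))


def rolling_weighted_mean(
    values: np.ndarray,
    weights: FrameWeights | np.ndarray,
) -> np.ndarray:
    """Running weighted mean A_w(n) = sum_{t<=n} A_t w_t / sum_{t<=n} w_t.

    The final element equals the batch weighted mean.
    """
    values = np.asarray(values, dtype=float)
    w = weights.w if isinstance(weights, FrameWeights) else np.asarray(weights, float)
    if len(values) != len(w):
        raise ValueError("values and weights must have equal length")
    cum_w = np.cumsum(w)
    if cum_w[-1] <= 0:
        raise ValueError("total weight is zero")
    return np.cumsum(values * w) / cum_w


def weighted_mean(
    values: np.ndarray,
    weights: FrameWeights | np.ndarray,
) -> float:
    """Batch weighted mean (the last element of the rolling estimate)."""
    return float(rolling_weighted_mean(values, weights)[-1])
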