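"""Normalized sum/difference representation of the 2-D wrist angle.

Self-paced subjects drift diagonally, so the two wrist axes are first
normalized by their absolute maxima over the training data and then combined
into a sum and a difference coordinate,

    u = x/max_x + y/max_y,      v = x/max_x - y/max_y,

which aligns the regression targets with the diagonals the movements
actually follow.  The transform is linear and exactly invertible:

    x = max_x (u + v) / 2,      y = max_y (u - v) / 2.

Sign convention: angle X is flexion-extension with extension positive,
angle Y is radial-ulnar deviation with radial positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError

__all__ = [
    "AngleNormalizer",
    "fit_normalization",
    "to_sum_diff",
    "from_sum_diff",
]


def fit_normalization(angles: np.ndarray) -> tuple[float, float]:
    """Per-axis absolute maxima of a training angle set.

    ``angles`` is an (n, 2) array in degrees, or a list of such arrays
    (stacked before taking maxima).
    """
    if isinstance(angles, (list, tuple)):
        angles = np.vstack(angles)
    angles = np.asarray(angles, dtype=float)
    max_x = float(np.max(np.abs(angles[:, 0])))
    max_y = float(np.max(np.abs(angles[:, 1])))
    if max_x <= 0 or max_y <= 0:
        axis = "X" if max_x <= 0 else "Y"
        raise DegenerateDataError(
            f"angle axis {axis} has zero range in the training set"
        )
    return max_x, max_y


def to_sum_diff(angles: np.ndarray, max_x: float, max_y: float) -> np.ndarray:
    """Map (n, 2) angles in degrees to (n, 2) sum/difference coordinates."""
    if max_x <= 0 or max_y <= 0:
        raise ValueError("normalization maxima must be positive")
    angles = np.asarray(angles, dtype=float)
    xn = angles[..., 0] / max_x
    yn = angles[..., 1] / max_y
    return np.stack([xn + yn, xn - yn], axis=-1)


def from_sum_diff(uv: np.ndarray, max_x: float, max_y: float) -> np.ndarray:
    """Exact inverse of :func:`to_sum_diff`."""
    if max_x <= 0 or max_y <= 0:
        raise ValueError("normalization maxima must be positive")
    uv = np.asarray(uv, dtype=float)
    x = max_x * (uv[..., 0] + uv[..., 1]) / 2.0
    y = max_y * (uv[..., 0] - uv[..., 1]) / 2.0
    return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class AngleNormalizer:
    """Frozen normalization constants estimated on training trials only."""

    max_x: float
    max_y: float

    @classmethod
    def fit(cls, angles) -> "AngleNormalizer":
        return cls(*fit_normalization(angles))

    def forward(self, angles: np.ndarray) -> np.ndarray:
        return to_sum_diff(angles, self.max_x, self.max_y)

    def inverse(self, uv: np.ndarray) -> np.ndarray:
        return from_sum_diff(uv, self.max_x, self.max_y)
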