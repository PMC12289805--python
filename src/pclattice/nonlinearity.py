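"""Logistic activation: value, derivatives, and inverse.

Every other module evaluates its nonlinearity through the functions here.
All functions accept scalars or numpy arrays and broadcast elementwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SigmoidParams",
    "sigmoid",
    "sigmoid_deriv",
    "sigmoid_second_deriv",
    "sigmoid_inverse",
]

#: Clipping guard for the inverse: arguments in [0, EPS) or (1-EPS, 1] are
#: clipped before inversion (the top boundary condition inverts a state that
#: saturates numerically toward the up state).
INVERSE_GUARD = 1e-12

_warned_clip = False


@dataclass(frozen=True)
class SigmoidParams:
    """Slope ``mu`` and threshold ``theta`` of the logistic activation."""

    mu: float
    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or self.mu <= 0:
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not np.isfinite(self.theta) or self.theta < 0:
            raise ValueError(f"theta must be >= 0 and finite, got {self.theta}")


def _check_finite(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid argument must be finite")
    return x


def sigmoid(x, params: SigmoidParams):
    """S(x) = 1 / (1 + exp(-mu (x - theta))), overflow-safe for any real x."""
    x = _check_finite(x)
    out = expit(params.mu * (x - params.theta))
    return out if out.ndim else float(out)


def sigmoid_deriv(x, params: SigmoidParams):
    """S'(x) = mu S(x) (1 - S(x)); strictly positive."""
    x = _check_finite(x)
    s = expit(params.mu * (x - params.theta))
    out = params.mu * s * (1.0 - s)
    return out if out.ndim else float(out)


def sigmoid_second_deriv(x, params: SigmoidParams):
    """S''(x) = mu^2 S (1 - S)(1 - 2S); vanishes at x = theta."""
    x = _check_finite(x)
    s = expit(params.mu * (x - params.theta))
    out = params.mu**2 * s * (1.0 - s) * (1.0 - 2.0 * s)
    return out if out.ndim else float(out)


def sigmoid_inverse(y, params: SigmoidParams, guard: float = INVERSE_GUARD):
    """S^{-1}(y) = theta + log(y / (1-y)) / mu.

    Arguments in ``[0, guard)`` or ``(1-guard, 1]`` are clipped to the guard
    before inversion (a warning is emitted once per process); values outside
    [0, 1] raise ``ValueError``.
    """
    global _warned_clip
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("sigmoid_inverse argument must be finite")
    if np.any(y < 0.0) or np.any(y > 1.0):
        raise ValueError("sigmoid_inverse argument outside [0, 1]")
    if np.any(y < guard) or np.any(y > 1.0 - guard):
        if not _warned_clip:
            warnings.warn(
                "sigmoid_inverse argument clipped to the guard interval "
                f"[{guard}, {1 - guard}]",
                RuntimeWarning,
                stacklevel=2,
            )
            _warned_clip = True
        y = np.clip(y, guard, 1.0 - guard)
    out = params.theta + np.log(y / (1.0 - y)) / params.mu
    return out if out.ndim else float(out)
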