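"""Right-hand sides of the model variants.

Variants:

* ``local_map`` — the scalar three-point nonlinear coupling map; building
  block of every scalar variant.
* ``scalar_rhs`` — finite hierarchy of J scalar layers with input closure
  ``v_0 = s_0(t)`` at the bottom and the artificial unknown
  ``v_{J+1} = S^{-1}(v_J)`` at the top (which cancels the feedback term of
  layer J identically; the cancellation is implemented symbolically).
* ``bi_infinite_rhs`` — truncation of the lattice on all of Z with both ghost
  ends clamped to prescribed equilibrium values (fronts converge
  exponentially to the equilibria, so clamping is the faithful truncation).
* ``vector_rhs`` — the d-population model with weight matrices, in physical
  (unrescaled) time.
* ``diagonal_rhs`` — the scalar reduction for diagonal weight matrices with
  entries (omega_f, omega_b).
* ``adaptation_rhs`` — scalar model augmented with a linear spike-frequency
  adaptation variable per layer.

All state inputs are numpy arrays; protocols are objects exposing
``value(t)`` (see :mod:`pclattice.simulate`) or plain callables ``t -> s0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import HyperParams, ModelParams
from .nonlinearity import SigmoidParams, sigmoid, sigmoid_deriv

__all__ = [
    "VectorModelParams",
    "DiagonalWeights",
    "AdaptationParams",
    "local_map",
    "scalar_rhs",
    "bi_infinite_rhs",
    "vector_rhs",
    "diagonal_rhs",
    "adaptation_rhs",
]


def _input_fn(protocol):
    return protocol.value if hasattr(protocol, "value") else protocol


@dataclass(frozen=True)
class VectorModelParams:
    """d-population model: weight matrices, raw gains, and activation."""

    d: int
    W_f: np.ndarray
    W_b: np.ndarray
    hyper: HyperParams
    sigmoid: SigmoidParams

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d >= 1 required")
        W_f = np.asarray(self.W_f, dtype=float)
        W_b = np.asarray(self.W_b, dtype=float)
        if W_f.shape != (self.d, self.d) or W_b.shape != (self.d, self.d):
            raise ValueError("W_f and W_b must be d x d matrices")
        if not (np.all(np.isfinite(W_f)) and np.all(np.isfinite(W_b))):
            raise ValueError("weight matrices must be finite")
        object.__setattr__(self, "W_f", W_f)
        object.__setattr__(self, "W_b", W_b)


@dataclass(frozen=True)
class DiagonalWeights:
    """Scalar feedforward / feedback weights; (1, 1) is the base model."""

    omega_f: float = 1.0
    omega_b: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.omega_f) and np.isfinite(self.omega_b)):
            raise ValueError("weights must be finite")


@dataclass(frozen=True)
class AdaptationParams:
    """Linear adaptation: strength gamma >= 0 and timescale tau_a > 0."""

    gamma: float
    tau_a: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError("gamma >= 0 required")
        if not np.isfinite(self.tau_a) or self.tau_a <= 0:
            raise ValueError("tau_a > 0 required")


def local_map(u, v, w, params: ModelParams):
    """Three-point coupling map

    ``N(u, v, w) = (1-p-q)(S(u)-v) + p S'(v)(u-S(v)) + q (S(w)-v)``

    where u is the layer below, v the layer itself, w the layer above.  On the
    diagonal ``N(v,v,v) = (-v+S(v))(1-p-pS'(v))``, the bistable reaction term.
    """
    sg = params.sigmoid
    sv = sigmoid(v, sg)
    return (
        (1.0 - params.p - params.q) * (sigmoid(u, sg) - v)
        + params.p * sigmoid_deriv(v, sg) * (u - sv)
        + params.q * (sigmoid(w, sg) - v)
    )


def scalar_rhs(state: np.ndarray, t: float, protocol, params: ModelParams) -> np.ndarray:
    """Finite-J scalar hierarchy; ``state[k]`` holds layer ``k+1``.

    Layer 1 sees the input ``s_0(t)`` as its lower neighbor; layer J has no
    incoming top-down signal, so its feedback term is omitted (the
    ``v_{J+1} = S^{-1}(v_J)`` closure makes it vanish identically).
    """
    v = np.asarray(state, dtype=float)
    J = v.shape[0]
    if J < 2:
        raise ValueError("at least 2 layers required")
    sg = params.sigmoid
    s0 = float(_input_fn(protocol)(t))

    u = np.empty(J)
    u[0] = s0
    u[1:] = v[:-1]

    sv = sigmoid(v, sg)
    dv = (1.0 - params.p - params.q) * (sigmoid(u, sg) - v) + params.p * sigmoid_deriv(
        v, sg
    ) * (u - sv)
    dv[:-1] += params.q * (sv[1:] - v[:-1])
    return dv


def bi_infinite_rhs(
    state: np.ndarray, t: float, params: ModelParams, left: float, right: float
) -> np.ndarray:
    """Truncated lattice on Z; ghost ends clamped to equilibria ``left``/``right``."""
    v = np.asarray(state, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("at least 2 layers required")
    sg = params.sigmoid

    u = np.empty_like(v)
    u[0] = left
    u[1:] = v[:-1]
    w = np.empty_like(v)
    w[-1] = right
    w[:-1] = v[1:]

    sv = sigmoid(v, sg)
    return (
        (1.0 - params.p - params.q) * (sigmoid(u, sg) - v)
        + params.p * sigmoid_deriv(v, sg) * (u - sv)
        + params.q * (sigmoid(w, sg) - v)
    )


def vector_rhs(
    state: np.ndarray, t: float, protocol, vparams: VectorModelParams
) -> np.ndarray:
    """d-population hierarchy in physical time; ``state`` has shape (d, J).

    Implements the three layer cases (input-adjacent, interior, top) with
    feedforward drive ``beta (W_f S(V_{j-1}) - V_j)``, feedforward error
    correction ``alpha DS(V_j) W_b^T (V_{j-1} - W_b S(V_j))`` and feedback
    ``lambda (W_b S(V_{j+1}) - V_j)``; the top layer has no feedback term.
    """
    V = np.asarray(state, dtype=float)
    if V.ndim != 2 or V.shape[0] != vparams.d:
        raise ValueError(f"state must have shape (d, J) with d={vparams.d}")
    d, J = V.shape
    if J < 2:
        raise ValueError("at least 2 layers required")
    sg = vparams.sigmoid
    h = vparams.hyper
    W_f, W_b = vparams.W_f, vparams.W_b

    s0 = np.broadcast_to(np.asarray(_input_fn(protocol)(t), dtype=float), (d,))
    below = np.empty_like(V)  # V_{j-1} for each layer
    below[:, 0] = s0
    below[:, 1:] = V[:, :-1]

    SV = sigmoid(V, sg)
    drive = h.beta * (W_f @ sigmoid(below, sg) - V)
    err = h.alpha * sigmoid_deriv(V, sg) * (W_b.T @ (below - W_b @ SV))
    dV = drive + err
    dV[:, :-1] += h.lambda_ * (W_b @ SV[:, 1:] - V[:, :-1])
    return dV


def diagonal_rhs(
    state: np.ndarray,
    t: float,
    protocol,
    hyper: HyperParams,
    sg: SigmoidParams,
    weights: DiagonalWeights,
) -> np.ndarray:
    """Scalar chain with diagonal weights (omega_f, omega_b), physical time:

    ``v_j' = beta (w_f S(v_{j-1}) - v_j) + alpha S'(v_j) w_b (v_{j-1} - w_b S(v_j))
    + lambda (w_b S(v_{j+1}) - v_j)``; top layer drops the feedback term.
    """
    v = np.asarray(state, dtype=float)
    J = v.shape[0]
    if J < 2:
        raise ValueError("at least 2 layers required")
    wf, wb = weights.omega_f, weights.omega_b

    u = np.empty(J)
    u[0] = float(_input_fn(protocol)(t))
    u[1:] = v[:-1]

    sv = sigmoid(v, sg)
    dv = hyper.beta * (wf * sigmoid(u, sg) - v) + hyper.alpha * sigmoid_deriv(v, sg) * (
        wb * (u - wb * sv)
    )
    dv[:-1] += hyper.lambda_ * (wb * sv[1:] - v[:-1])
    return dv


def adaptation_rhs(
    state: tuple[np.ndarray, np.ndarray],
    t: float,
    protocol,
    params: ModelParams,
    ap: AdaptationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Scalar hierarchy with per-layer linear adaptation:

    ``v' = N(...) - gamma a``, ``a' = (v - a) / tau_a``.  With gamma = 0 the
    activity equations coincide with :func:`scalar_rhs`.
    """
    v, a = state
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    if v.shape != a.shape:
        raise ValueError("activity and adaptation vectors must share a shape")
    dv = scalar_rhs(v, t, protocol, params) - ap.gamma * a
    da = (v - a) / ap.tau_a
    return dv, da
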