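"""Stationary homogeneous states, fold points, and linear stability.

The homogeneous equilibria of the lattice solve ``x = S(x)``, which inverts to
the explicit threshold parametrization ``theta = f(x) = x + log((1-x)/x)/mu``.
For ``mu > 4`` the map ``f`` has exactly three monotonicity intervals, giving
up to three coexisting branches (down / middle / up); the window where all
three coexist is the bistable regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import brentq

from .nonlinearity import SigmoidParams, sigmoid, sigmoid_deriv

__all__ = [
    "HyperParams",
    "ModelParams",
    "BranchSet",
    "FoldPoints",
    "hyperparams_to_pq",
    "theta_of_x",
    "fold_points",
    "equilibrium_branches",
    "spectrum",
    "re_nu0",
    "classify_stability",
]

_ROOT_EPS = 1e-14
_ROOT_TOL = 1e-12
_TIE_TOL = 1e-10


@dataclass(frozen=True)
class HyperParams:
    """Raw gains: feedforward error correction (alpha), instantaneous
    feedforward drive (beta), feedback error correction (lambda_)."""

    alpha: float
    beta: float
    lambda_: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lambda_"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.alpha + self.beta + self.lambda_ <= 0:
            raise ValueError(
                "degenerate dynamics: alpha + beta + lambda must be positive"
            )


def hyperparams_to_pq(h: HyperParams) -> tuple[float, float, float]:
    """Reduce raw gains to relative strengths (p, q) and the time scale.

    ``p = alpha / (alpha+beta+lambda)``, ``q = lambda / (alpha+beta+lambda)``;
    time in the reduced model is physical time multiplied by the returned
    scale ``alpha+beta+lambda``.
    """
    total = h.alpha + h.beta + h.lambda_
    return h.alpha / total, h.lambda_ / total, total


@dataclass(frozen=True)
class ModelParams:
    """Reduced parameter tuple (theta, mu, p, q).

    Admissibility: ``mu > 4``, ``0 <= p < 4/(4+mu)``, ``0 <= q <= 1`` and
    ``p + q <= 1``.  Membership in the bistable set additionally requires
    ``theta_star(mu) < theta < theta_star_upper(mu)``
    (see :meth:`in_bistable_window`).
    """

    theta: float
    mu: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or self.mu <= 4:
            raise ValueError(f"mu > 4 required (got mu={self.mu})")
        if not np.isfinite(self.theta) or self.theta < 0:
            raise ValueError(f"theta >= 0 required (got theta={self.theta})")
        p_max = 4.0 / (4.0 + self.mu)
        if not 0 <= self.p < p_max:
            raise ValueError(
                f"p must satisfy 0 <= p < 4/(4+mu) = {p_max:.6g} (got p={self.p})"
            )
        if not 0 <= self.q <= 1:
            raise ValueError(f"q must lie in [0, 1] (got q={self.q})")
        if self.p + self.q > 1:
            raise ValueError(f"p + q <= 1 required (got p+q={self.p + self.q})")

    @property
    def sigmoid(self) -> SigmoidParams:
        return SigmoidParams(mu=self.mu, theta=self.theta)

    def in_bistable_window(self) -> bool:
        fp = fold_points(self.mu)
        return fp.theta_star < self.theta < fp.theta_star_upper


class FoldPoints(NamedTuple):
    x_star: float
    x_star_upper: float
    theta_star: float
    theta_star_upper: float


@dataclass(frozen=True)
class BranchSet:
    """Equilibrium branches and fold data at fixed (theta, mu).

    Absent branches are ``None``.  When ``bistable`` all three values are
    present and ordered ``0 < x_d < x_star < x_m < x_star_upper < x_u < 1``.
    """

    theta: float
    mu: float
    x_d: Optional[float]
    x_m: Optional[float]
    x_u: Optional[float]
    x_star: float
    x_star_upper: float
    theta_star: float
    theta_star_upper: float
    bistable: bool

    def branch(self, label: str) -> float:
        value = {"x_d": self.x_d, "x_m": self.x_m, "x_u": self.x_u}[label]
        if value is None:
            raise ValueError(f"branch {label!r} absent at theta={self.theta}")
        return value

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "mu": self.mu,
            "x_d": self.x_d,
            "x_m": self.x_m,
            "x_u": self.x_u,
            "x_star": self.x_star,
            "x_star_upper": self.x_star_upper,
            "theta_star": self.theta_star,
            "theta_star_upper": self.theta_star_upper,
            "bistable": self.bistable,
        }


def theta_of_x(x, mu: float):
    """Threshold parametrization ``f(x) = x + log((1-x)/x) / mu``, x in (0,1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("theta_of_x requires x in (0, 1)")
    out = x + np.log((1.0 - x) / x) / mu
    return out if out.ndim else float(out)


def fold_points(mu: float) -> FoldPoints:
    """Fold abscissae ``1/2 -+ sqrt(1/4 - 1/mu)`` and their thresholds."""
    if not np.isfinite(mu) or mu <= 4:
        raise ValueError(f"no bistable window: mu > 4 required (got {mu})")
    r = np.sqrt(0.25 - 1.0 / mu)
    x_star = 0.5 - r
    x_star_upper = 0.5 + r
    return FoldPoints(
        x_star=x_star,
        x_star_upper=x_star_upper,
        theta_star=theta_of_x(x_star, mu),
        theta_star_upper=theta_of_x(x_star_upper, mu),
    )


def _bracketed_root(theta: float, mu: float, lo: float, hi: float) -> float:
    return brentq(
        lambda x: theta_of_x(x, mu) - theta, lo, hi, xtol=_ROOT_TOL, rtol=8.9e-16
    )


def equilibrium_branches(theta: float, mu: float, tie_tol: float = _TIE_TOL) -> BranchSet:
    """Solve ``x = S(x)`` on each monotonicity interval of ``f``.

    ``f`` is decreasing on (0, x_star), increasing on (x_star, x_star_upper)
    and decreasing on (x_star_upper, 1), so each interval carries at most one
    root and bracketed root-finding is guaranteed to converge.  Within
    ``tie_tol`` of a fold threshold the merging pair is reported once (as the
    fold abscissa) and ``bistable`` is False.
    """
    fp = fold_points(mu)
    x_d = x_m = x_u = None

    if abs(theta - fp.theta_star) < tie_tol:
        # down and middle branches collapse at the lower fold
        x_d = fp.x_star
        x_u = _bracketed_root(theta, mu, fp.x_star_upper, 1.0 - _ROOT_EPS)
    elif abs(theta - fp.theta_star_upper) < tie_tol:
        # middle and up branches collapse at the upper fold
        x_u = fp.x_star_upper
        x_d = _bracketed_root(theta, mu, _ROOT_EPS, fp.x_star)
    else:
        if theta > fp.theta_star:
            x_d = _bracketed_root(theta, mu, _ROOT_EPS, fp.x_star)
        if fp.theta_star < theta < fp.theta_star_upper:
            x_m = _bracketed_root(theta, mu, fp.x_star, fp.x_star_upper)
        if theta < fp.theta_star_upper:
            x_u = _bracketed_root(theta, mu, fp.x_star_upper, 1.0 - _ROOT_EPS)

    return BranchSet(
        theta=theta,
        mu=mu,
        x_d=x_d,
        x_m=x_m,
        x_u=x_u,
        x_star=fp.x_star,
        x_star_upper=fp.x_star_upper,
        theta_star=fp.theta_star,
        theta_star_upper=fp.theta_star_upper,
        bistable=x_d is not None and x_m is not None and x_u is not None,
    )


_EQUILIBRIUM_RTOL = 1e-8  # looser than root tolerance to admit simulated fixed points


def _check_equilibrium(x: float, params: ModelParams) -> None:
    if abs(x - sigmoid(x, params.sigmoid)) >= _EQUILIBRIUM_RTOL:
        raise ValueError(
            f"x={x} is not an equilibrium: |x - S(x)| >= {_EQUILIBRIUM_RTOL}"
        )


def spectrum(x: float, params: ModelParams, phi) -> complex:
    """Growth rate nu(phi) of the Fourier mode ``exp(nu t + i phi j)`` of the
    linearization around a homogeneous equilibrium ``x``.

    ``nu(phi) = (1-q) S'(x) e^{-i phi} - (1-p) - p S'(x)^2 + q S'(x) e^{i phi}``.
    Its real part is maximal at phi = 0.
    """
    _check_equilibrium(x, params)
    phi = np.asarray(phi, dtype=float)
    sp = sigmoid_deriv(x, params.sigmoid)
    out = (
        (1.0 - params.q) * sp * np.exp(-1j * phi)
        - (1.0 - params.p)
        - params.p * sp**2
        + params.q * sp * np.exp(1j * phi)
    )
    return out if out.ndim else complex(out)


def re_nu0(x: float, params: ModelParams) -> float:
    """Maximal spectral growth rate ``Re nu(0) = (S'(x)-1)(1-p-p S'(x))``."""
    _check_equilibrium(x, params)
    sp = sigmoid_deriv(x, params.sigmoid)
    return (sp - 1.0) * (1.0 - params.p - params.p * sp)


_MARGINAL_TOL = 1e-8


def classify_stability(branch_label: str, branch_set: BranchSet, params: ModelParams) -> str:
    """Classify a branch as ``"stable"``/``"unstable"`` from the sign of
    Re nu(0); returns ``"marginal"`` at a fold degeneracy."""
    x = branch_set.branch(branch_label)
    rate = re_nu0(x, params)
    if abs(rate) < _MARGINAL_TOL:
        return "marginal"
    return "stable" if rate < 0 else "unstable"
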