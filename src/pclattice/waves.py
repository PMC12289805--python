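"""Front-speed estimation, pinning detection, profiles, and sign maps.

From step initial data the solution converges exponentially to a translate of
the traveling front, so the late-time drift of the interface (tracked as the
level crossing of the unstable middle state) estimates the wave speed.  A
front is *pinned* when both its fitted speed is below the pinning tolerance
and its total displacement over the fit window is below one layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .equilibria import BranchSet, ModelParams, equilibrium_branches
from .lattice_model import bi_infinite_rhs
from .simulate import (
    DEFAULT_J,
    DEFAULT_OUTPUT_DT,
    DEFAULT_T_FINAL,
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    StepInitialCondition,
    Trajectory,
    integrate,
    make_initial,
)

__all__ = [
    "SpeedEstimate",
    "WaveProfile",
    "SignMap",
    "interface_position",
    "estimate_speed",
    "extract_profile",
    "sign_map",
]

PINNING_TOL = 5e-3
PINNING_DISPLACEMENT = 1.0
SENTINEL_MARGIN = 50
TRANSIENT_FRACTION = 0.25
STDERR_GATE = 1e-3


class FrontLeftWindowError(RuntimeError):
    """The tracked interface reached the sentinel margin of the truncation."""


@dataclass
class SpeedEstimate:
    """Least-squares front speed with fit diagnostics.

    ``positions`` are interface positions (lattice coordinates) at ``times``;
    the fit uses the window ``window = (t_start, t_end)``.
    """

    c: float
    stderr: float
    window: tuple[float, float]
    pinned: bool
    positions: np.ndarray
    times: np.ndarray
    direction: str
    params: Optional[ModelParams] = None
    trajectory: Optional[Trajectory] = None

    @property
    def sign(self) -> int:
        return 0 if self.pinned else int(np.sign(self.c))

    def to_dict(self) -> dict:
        return {
            "c": self.c,
            "stderr": self.stderr,
            "window": list(self.window),
            "pinned": self.pinned,
            "sign": self.sign,
            "direction": self.direction,
            "params": None if self.params is None else vars(self.params),
        }


@dataclass
class WaveProfile:
    """Co-moving front profile sampled on the offset grid xi = j - c t."""

    offsets: np.ndarray
    values: np.ndarray
    direction: str


@dataclass
class SignMap:
    """Joint sign classification of both wave speeds over a parameter grid."""

    axes: tuple[str, str]
    grids: tuple[np.ndarray, np.ndarray]
    table: pd.DataFrame

    def sign_matrix(self, which: str) -> np.ndarray:
        col = {"u_to_d": "sign_ud", "d_to_u": "sign_du"}[which]
        n0, n1 = len(self.grids[0]), len(self.grids[1])
        return self.table[col].to_numpy().reshape(n0, n1)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def interface_position(snapshot: np.ndarray, level: float) -> float:
    """Fractional array index where the profile crosses ``level``.

    Linear interpolation between the two bracketing layers; the first crossing
    is returned (monotone fronts cross exactly once).  Raises if the snapshot
    never crosses the level.
    """
    d = np.asarray(snapshot, dtype=float) - level
    on = np.nonzero(d == 0.0)[0]
    if on.size:
        return float(on[0])
    cross = np.nonzero(d[:-1] * d[1:] < 0)[0]
    if cross.size == 0:
        raise ValueError("front left the window or never formed (no level crossing)")
    i = int(cross[0])
    return i + d[i] / (d[i] - d[i + 1])


def _ols_slope(t: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error from ordinary least squares."""
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ coef
    dof = max(len(t) - 2, 1)
    sxx = np.sum((t - t.mean()) ** 2)
    stderr = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if sxx > 0 else np.inf
    return float(coef[0]), stderr


def estimate_speed(
    params: ModelParams,
    direction: str,
    J: int = DEFAULT_J,
    t_final: float = DEFAULT_T_FINAL,
    output_dt: float = DEFAULT_OUTPUT_DT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
    transient_fraction: float = TRANSIENT_FRACTION,
    pinning_tol: float = PINNING_TOL,
    margin: int = SENTINEL_MARGIN,
    keep_trajectory: bool = False,
    branch_set: Optional[BranchSet] = None,
) -> SpeedEstimate:
    """Simulate the truncated bi-infinite lattice from step data and fit the
    late-time interface drift.

    The interface is tracked at level ``x_m`` (the separatrix); the OLS fit
    runs on t >= ``transient_fraction * t_final``.  Raises
    :class:`FrontLeftWindowError` if the interface comes within ``margin``
    layers of either truncation boundary.
    """
    if direction not in ("u_to_d", "d_to_u"):
        raise ValueError("direction must be 'u_to_d' or 'd_to_u'")
    bs = branch_set if branch_set is not None else equilibrium_branches(params.theta, params.mu)
    if not bs.bistable:
        raise ValueError("wave speeds require parameters in the bistable window")

    offset = -(J // 2)
    init = make_initial(StepInitialCondition(direction, interface_index=0), bs, J, offset)
    left, right = init[0], init[-1]
    traj = integrate(
        lambda t, y: bi_infinite_rhs(y, t, params, left, right),
        init,
        t_final,
        output_dt=output_dt,
        rtol=rtol,
        atol=atol,
        method=method,
        params=params,
        truncation={"J": J, "offset": offset, "boundary": "clamped",
                    "geometry": "bi_infinite"},
    )

    positions = np.empty(len(traj.times))
    for k in range(len(traj.times)):
        pos = interface_position(traj.snapshot(k), bs.x_m)
        if pos < margin or pos > J - 1 - margin:
            raise FrontLeftWindowError(
                f"interface within {margin} layers of the boundary at "
                f"t={traj.times[k]:.1f}; increase J or reduce t_final"
            )
        positions[k] = pos + offset

    mask = traj.times >= transient_fraction * t_final
    t_fit, x_fit = traj.times[mask], positions[mask]
    c, stderr = _ols_slope(t_fit, x_fit)
    displacement = float(x_fit[-1] - x_fit[0])
    pinned = bool(abs(displacement) < PINNING_DISPLACEMENT and abs(c) < pinning_tol)

    return SpeedEstimate(
        c=c,
        stderr=stderr,
        window=(float(t_fit[0]), float(t_fit[-1])),
        pinned=pinned,
        positions=positions,
        times=traj.times,
        direction=direction,
        params=params,
        trajectory=traj if keep_trajectory else None,
    )


def extract_profile(
    trajectory: Trajectory,
    estimate: SpeedEstimate,
    n_snapshots: int = 20,
    stderr_gate: float = STDERR_GATE,
) -> WaveProfile:
    """Resample late-time snapshots into the co-moving frame xi = j - c t.

    Averages the last ``n_snapshots`` snapshots of the fit window after
    shifting each by c t; successive snapshots must collapse onto one curve.
    """
    if estimate.pinned:
        raise ValueError("no traveling profile: the front is pinned")
    if estimate.stderr > stderr_gate:
        raise ValueError(
            f"fit stderr {estimate.stderr:.2e} above the quality gate {stderr_gate}"
        )
    offset = trajectory.truncation.get("offset", 0)
    j = offset + np.arange(trajectory.n_layers)
    t0, t1 = estimate.window
    idx = np.nonzero((trajectory.times >= t0) & (trajectory.times <= t1))[0][-n_snapshots:]

    # common offset grid: intersection of the shifted index ranges
    lo = max(j[0] - estimate.c * trajectory.times[k] for k in idx)
    hi = min(j[-1] - estimate.c * trajectory.times[k] for k in idx)
    xi = np.arange(np.ceil(lo), np.floor(hi) + 0.5, 0.5)

    samples = np.empty((len(idx), len(xi)))
    for row, k in enumerate(idx):
        shifted = j - estimate.c * trajectory.times[k]
        samples[row] = np.interp(xi, shifted, trajectory.snapshot(k))
    return WaveProfile(offsets=xi, values=samples.mean(axis=0),
                       direction=estimate.direction)


def sign_map(
    axes: tuple[str, str],
    grids: tuple[np.ndarray, np.ndarray],
    fixed: dict,
    pinning_tol: float = PINNING_TOL,
    **speed_kwargs,
) -> SignMap:
    """Estimate both wave speeds at every node of a 2-D parameter grid.

    ``axes`` names two of {"theta", "mu", "p", "q"}; ``fixed`` supplies the
    others.  Inadmissible nodes (outside the bistable window or the allowed
    p-range) are marked missing rather than fatal.  Nodes are independent;
    serial evaluation order does not affect results.
    """
    g0 = np.asarray(grids[0], dtype=float)
    g1 = np.asarray(grids[1], dtype=float)
    if np.any(np.diff(g0) <= 0) or np.any(np.diff(g1) <= 0):
        raise ValueError("grids must be strictly increasing")

    rows = []
    for a in g0:
        for b in g1:
            values = {**fixed, axes[0]: a, axes[1]: b}
            row = {k: values[k] for k in ("theta", "q", "p", "mu")}
            try:
                params = ModelParams(**values)
                if not params.in_bistable_window():
                    raise ValueError("outside bistable window")
                ud = estimate_speed(params, "u_to_d", pinning_tol=pinning_tol,
                                    **speed_kwargs)
                du = estimate_speed(params, "d_to_u", pinning_tol=pinning_tol,
                                    **speed_kwargs)
                row.update(
                    c_ud=ud.c, c_ud_stderr=ud.stderr, pinned_ud=ud.pinned,
                    c_du=du.c, c_du_stderr=du.stderr, pinned_du=du.pinned,
                    sign_ud=ud.sign, sign_du=du.sign,
                )
            except (ValueError, FrontLeftWindowError):
                row.update(
                    c_ud=np.nan, c_ud_stderr=np.nan, pinned_ud=None,
                    c_du=np.nan, c_du_stderr=np.nan, pinned_du=None,
                    sign_ud=np.nan, sign_du=np.nan,
                )
            rows.append(row)

    table = pd.DataFrame(
        rows,
        columns=["theta", "q", "p", "mu", "c_ud", "c_ud_stderr", "pinned_ud",
                 "c_du", "c_du_stderr", "pinned_du", "sign_ud", "sign_du"],
    )
    return SignMap(axes=axes, grids=(g0, g1), table=table)
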