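"""Semi-infinite network experiments: outcome classification and threshold
bisection for input amplitude (s0*), flash duration (tau*), and the pinning
boundary parameters (q0, theta0), in both orientations.

Orientation mapping: in both the bottom-up (layers 1..J, input below) and
top-down (layers -1..-J, input above) systems, array position k holds the
layer at distance k+1 from the input, so every classification rule is written
once in "distance from input" coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .equilibria import BranchSet, ModelParams, equilibrium_branches
from .lattice_model import scalar_rhs
from .simulate import (
    InputProtocol,
    StepInitialCondition,
    Trajectory,
    integrate,
    make_initial,
    top_down_rhs,
)
from .waves import FrontLeftWindowError, PINNING_TOL, estimate_speed

__all__ = [
    "REGIME_LABELS",
    "ThresholdResult",
    "StationaryProfile",
    "UndeterminedOutcomeError",
    "simulate_semi",
    "classify_outcome",
    "stationary_profile",
    "find_s0_star",
    "find_tau_star",
    "find_pinning_boundary",
    "regime_map",
]

REGIME_LABELS = (
    "stagnation",
    "front_propagation",
    "stacked_propagation",
    "pulse_propagation",
    "propagation_failure",
)

SENTINEL_OFFSET = 20          # sentinel layer = distance J-20 from the input
STAGNATION_DERIV_TOL = 1e-8
FAILURE_DIST_TOL = 1e-3
TRAILING_ADVANCE = 5.0
S0_TOL = 1e-3
TAU_TOL = 1e-2
BOUNDARY_TOL = 1e-3
S0_CAP = 10.0
TAU_CAP = 200.0

#: default truncation / horizon for classification runs (propagating fronts at
#: |c| <= 1 stay clear of the sentinel over this horizon)
CLASSIFY_J = 200
CLASSIFY_T_FINAL = 150.0

#: reduced-scale speed estimation used for threshold preconditions
_SPEED_KW = dict(J=250, t_final=125.0)


class UndeterminedOutcomeError(RuntimeError):
    """No classification rule fired by t_final; retry with a longer horizon."""


@dataclass(frozen=True)
class ThresholdResult:
    """Bisection outcome: ``lo < value < hi`` with ``hi - lo <= 2 tol`` and
    differing outcomes at the bracket ends."""

    kind: str            # s0_star | tau_star | q0 | theta0
    value: float
    bracket: tuple[float, float]
    tol: float
    direction: str       # bottom_up | top_down
    params: dict

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "value": self.value,
            "bracket": list(self.bracket),
            "tol": self.tol,
            "direction": self.direction,
            "params": self.params,
        }


@dataclass
class StationaryProfile:
    """Stationary solution of the semi-infinite system anchored at s0."""

    values: np.ndarray
    anchor: float
    tail: str            # down | up
    direction: str
    residual: float


def _semi_rhs(direction: str, protocol, params: ModelParams, tail: float):
    if direction == "bottom_up":
        return lambda t, y: scalar_rhs(y, t, protocol, params)
    if direction == "top_down":
        return lambda t, y: top_down_rhs(y, t, protocol, params, tail=tail)
    raise ValueError("direction must be 'bottom_up' or 'top_down'")


def simulate_semi(
    params: ModelParams,
    protocol: InputProtocol,
    direction: str,
    branch_set: Optional[BranchSet] = None,
    J: int = CLASSIFY_J,
    t_final: float = CLASSIFY_T_FINAL,
    initial: Optional[np.ndarray] = None,
    tail_value: Optional[float] = None,
    **integrate_kwargs,
) -> Trajectory:
    """Integrate the semi-infinite truncation from all-down data (default)."""
    bs = branch_set if branch_set is not None else equilibrium_branches(params.theta, params.mu)
    if initial is None:
        initial = make_initial(StepInitialCondition("all_down"), bs, J)
    tail = bs.x_d if tail_value is None else tail_value
    geometry = direction
    boundary = "sigmoid_inverse" if direction == "bottom_up" else "clamped_tail"
    return integrate(
        _semi_rhs(direction, protocol, params, tail),
        initial,
        t_final,
        breakpoints=protocol.breakpoints(),
        params=params,
        protocol=protocol,
        truncation={"J": J, "offset": 1 if direction == "bottom_up" else -1,
                    "boundary": boundary, "geometry": geometry, "tail": tail},
        **integrate_kwargs,
    )


def _deriv_sup(trajectory: Trajectory, k: int) -> float:
    params = trajectory.params
    protocol = trajectory.protocol
    direction = trajectory.truncation["geometry"]
    tail = trajectory.truncation.get("tail", 0.0)
    rhs = _semi_rhs(direction, protocol, params, tail)
    return float(np.max(np.abs(rhs(trajectory.times[k], trajectory.snapshot(k)))))


def _crossings(snapshot: np.ndarray, level: float) -> np.ndarray:
    """Fractional positions of all level crossings of a snapshot."""
    d = snapshot - level
    idx = np.nonzero(d[:-1] * d[1:] < 0)[0]
    return idx + d[idx] / (d[idx] - d[idx + 1])


def _fit_slope(t: np.ndarray, x: np.ndarray) -> float:
    if len(t) < 2:
        return 0.0
    return float(np.polyfit(t, x, 1)[0])


def classify_outcome(
    trajectory: Trajectory,
    branch_set: BranchSet,
    protocol: InputProtocol,
    direction: str,
    pinning_tol: float = PINNING_TOL,
) -> str:
    """Classify a semi-infinite run into one of :data:`REGIME_LABELS`.

    Rules (in "distance from input" coordinates, sentinel at J-20):

    * front_propagation — the sentinel layer exceeds (x_m+x_u)/2 and, for
      constant input, remains above it at t_final;
    * stagnation — time-derivative sup-norm < 1e-8 at t_final and every layer
      beyond distance 20 sits below x_m;
    * propagation_failure (flashed) — the state returns uniformly to the down
      state (sup distance < 1e-3) before the sentinel is reached;
    * stacked_propagation / pulse_propagation (flashed) — the sentinel is
      reached and a trailing up-crossing interface also advances; a pulse has
      both interfaces moving at the same speed with constant width.
    """
    x_d, x_m, x_u = branch_set.x_d, branch_set.x_m, branch_set.x_u
    level_up = 0.5 * (x_m + x_u)
    J = trajectory.n_layers
    sentinel = J - SENTINEL_OFFSET - 1  # array index of the layer at distance J-20
    times = trajectory.times
    values = trajectory.values

    sentinel_series = values[sentinel]
    reached = np.nonzero(sentinel_series > level_up)[0]

    if protocol.kind != "flashed":
        if reached.size and sentinel_series[-1] > level_up:
            return "front_propagation"
        deriv = _deriv_sup(trajectory, len(times) - 1)
        if deriv < STAGNATION_DERIV_TOL and np.all(values[SENTINEL_OFFSET:, -1] < x_m):
            return "stagnation"
        raise UndeterminedOutcomeError(
            f"no rule fired by t_final={times[-1]}: sentinel "
            f"{sentinel_series[-1]:.4f}, deriv sup {deriv:.2e}"
        )

    # flashed protocol: classification starts after the flash ends
    post = np.nonzero(times > protocol.tau)[0]
    if post.size == 0:
        raise UndeterminedOutcomeError("horizon shorter than the flash duration")
    reach_k = reached[0] if reached.size else None

    sup_dist = np.max(np.abs(values[:, post] - x_d), axis=0)
    dead = post[np.nonzero(sup_dist < FAILURE_DIST_TOL)[0]]
    if dead.size and (reach_k is None or dead[0] < reach_k):
        return "propagation_failure"

    if reach_k is not None:
        # track leading (last) and trailing (first) x_m crossings after the flash
        t_tr, lead, trail = [], [], []
        for k in post:
            snap = values[:, k]
            cr = _crossings(snap, x_m)
            if cr.size == 0:
                continue
            lead_pos = cr[-1]
            trail_pos = cr[0] if (snap[0] < x_m and cr.size >= 2) else None
            if trail_pos is not None:
                t_tr.append(times[k])
                lead.append(lead_pos)
                trail.append(trail_pos)
        if t_tr:
            t_tr = np.asarray(t_tr)
            lead = np.asarray(lead)
            trail = np.asarray(trail)
            if trail[-1] - trail[0] >= TRAILING_ADVANCE:
                half = t_tr >= t_tr[0] + 0.5 * (t_tr[-1] - t_tr[0])
                c_lead = _fit_slope(t_tr[half], lead[half])
                c_trail = _fit_slope(t_tr[half], trail[half])
                width = lead[half] - trail[half]
                if (
                    abs(c_lead - c_trail) < pinning_tol
                    and width.max() - width.min() <= 2.0
                ):
                    return "pulse_propagation"
                return "stacked_propagation"
        return "front_propagation"

    raise UndeterminedOutcomeError(
        f"no rule fired by t_final={times[-1]} (flashed protocol)"
    )


def _classify_run(
    params: ModelParams,
    protocol: InputProtocol,
    direction: str,
    branch_set: BranchSet,
    J: int,
    t_final: float,
    max_doublings: int = 3,
    **kw,
) -> str:
    """Classification with automatic horizon doubling on 'undetermined'.

    Near a threshold the solution hovers close to the unstable stationary
    profile before resolving, so a few doublings may be needed for the
    bisection queries closest to the threshold.  Solver tolerances are
    tightened beyond the integration defaults so that the stagnation rule's
    1e-8 derivative criterion sits above the numerical noise floor.
    """
    kw.setdefault("rtol", 1e-10)
    kw.setdefault("atol", 1e-12)
    horizon = t_final
    for attempt in range(max_doublings + 1):
        traj = simulate_semi(params, protocol, direction, branch_set, J=J,
                             t_final=horizon, **kw)
        try:
            return classify_outcome(traj, branch_set, protocol, direction)
        except UndeterminedOutcomeError:
            if attempt == max_doublings:
                raise
            horizon *= 2.0


RESIDUAL_TOL = 1e-8
_TAIL_TOL = 1e-4


def stationary_profile(
    params: ModelParams,
    s0: float,
    tail: str,
    direction: str,
    J: int = CLASSIFY_J,
    chunk: float = 100.0,
    max_chunks: int = 40,
    deriv_tol: float = 1e-10,
) -> StationaryProfile:
    """Stationary solution anchored at the input, by long-time integration.

    ``tail`` selects the asymptotic state far from the input (``down`` or
    ``up``); the initial state is all-down (down tail) or all-up (up tail).
    Integration proceeds in chunks until the time-derivative sup-norm drops
    below ``deriv_tol``.
    """
    if tail not in ("down", "up"):
        raise ValueError("tail must be 'down' or 'up'")
    bs = equilibrium_branches(params.theta, params.mu)
    protocol = InputProtocol.constant(s0, baseline=bs.x_d)
    init_dir = "all_down" if tail == "down" else "all_up"
    state = make_initial(StepInitialCondition(init_dir), bs, J)
    tail_value = bs.x_d if tail == "down" else bs.x_u
    rhs = _semi_rhs(direction, protocol, params, tail_value)

    # tolerances well below deriv_tol so the stopping rule is not limited by
    # integrator accuracy
    for _ in range(max_chunks):
        traj = integrate(rhs, state, chunk, params=params, protocol=protocol,
                         rtol=1e-12, atol=1e-13)
        state = traj.final_state
        deriv = float(np.max(np.abs(rhs(0.0, state))))
        if deriv < deriv_tol:
            break
    else:
        raise RuntimeError(
            f"stationary profile did not converge within {max_chunks * chunk} "
            f"time units (deriv sup {deriv:.2e})"
        )

    residual = float(np.max(np.abs(rhs(0.0, state))))
    if residual >= RESIDUAL_TOL:
        raise RuntimeError(f"stationary residual {residual:.2e} above tolerance")
    target = bs.x_d if tail == "down" else bs.x_u
    if abs(state[-1] - target) > _TAIL_TOL:
        raise RuntimeError(
            f"tail layer {state[-1]:.6f} not within {_TAIL_TOL} of the "
            f"{tail} state {target:.6f}"
        )
    return StationaryProfile(values=state, anchor=s0, tail=tail,
                             direction=direction, residual=residual)


def _robust_speed(params: ModelParams, wave: str, kw: dict):
    """Speed estimate that halves the horizon when a fast front crosses the
    whole truncation window (such a front is unambiguously propagating)."""
    kw = dict(kw)
    for _ in range(5):
        try:
            return estimate_speed(params, wave, **kw)
        except FrontLeftWindowError:
            kw["t_final"] = kw.get("t_final", 125.0) / 2.0
            if kw["t_final"] < 10.0:
                raise
    raise FrontLeftWindowError("speed estimation failed at every tested horizon")


def find_s0_star(
    params: ModelParams,
    direction: str,
    tol: float = S0_TOL,
    J: int = CLASSIFY_J,
    t_final: float = CLASSIFY_T_FINAL,
    s0_cap: float = S0_CAP,
    speed_kwargs: Optional[dict] = None,
) -> ThresholdResult:
    """Minimal constant input amplitude for full propagation, by bisection.

    Defined only where the orientation-relevant front can invade
    (c_{u->d} > 0 bottom-up, c_{d->u} < 0 top-down); grows the upper bracket
    geometrically until propagation is observed (cap ``s0_cap``, consistent
    with s0* diverging at the pinning boundary).
    """
    bs = equilibrium_branches(params.theta, params.mu)
    kw = {**_SPEED_KW, **(speed_kwargs or {})}
    rel = _robust_speed(params, "u_to_d" if direction == "bottom_up" else "d_to_u", kw)
    good = rel.c > 0 if direction == "bottom_up" else rel.c < 0
    if rel.pinned or not good:
        raise ValueError(
            f"threshold undefined (pinned/adverse regime): relevant speed "
            f"c={rel.c:+.4f}, pinned={rel.pinned}"
        )

    def outcome(s0: float) -> str:
        protocol = InputProtocol.constant(s0, baseline=bs.x_d)
        return _classify_run(params, protocol, direction, bs, J, t_final)

    lo = bs.x_m                      # stagnation guaranteed (comparison principle)
    hi = bs.x_u
    while outcome(hi) != "front_propagation":
        hi = bs.x_m + 2.0 * (hi - bs.x_m)
        if hi > s0_cap:
            raise RuntimeError(
                f"no propagation below s0={s0_cap}: s0* diverges "
                "(parameters at or beyond the pinning boundary)"
            )
    while hi - lo > 2 * tol:
        mid = 0.5 * (lo + hi)
        if outcome(mid) == "front_propagation":
            hi = mid
        else:
            lo = mid
    return ThresholdResult(
        kind="s0_star", value=0.5 * (lo + hi), bracket=(lo, hi), tol=tol,
        direction=direction, params=vars(params),
    )


_PROPAGATING = ("front_propagation", "stacked_propagation", "pulse_propagation")


def find_tau_star(
    params: ModelParams,
    direction: str,
    s0: Optional[float] = None,
    tol: float = TAU_TOL,
    J: int = CLASSIFY_J,
    t_final: float = CLASSIFY_T_FINAL,
    tau_cap: float = TAU_CAP,
    speed_kwargs: Optional[dict] = None,
) -> ThresholdResult:
    """Minimal flash duration for full propagation at fixed amplitude
    (default: the up state), by bisection on tau."""
    bs = equilibrium_branches(params.theta, params.mu)
    kw = {**_SPEED_KW, **(speed_kwargs or {})}
    ud = _robust_speed(params, "u_to_d", kw)
    du = _robust_speed(params, "d_to_u", kw)
    if direction == "bottom_up":
        ok = (not ud.pinned and ud.c > 0) and du.c < ud.c
    else:
        ok = (not du.pinned and du.c < 0) and du.c < ud.c
    if not ok:
        raise ValueError(
            f"tau* undefined in this regime: c_ud={ud.c:+.4f}, c_du={du.c:+.4f}"
        )
    amplitude = bs.x_u if s0 is None else s0

    def outcome(tau: float) -> str:
        protocol = InputProtocol.flashed(amplitude, tau, baseline=bs.x_d)
        return _classify_run(params, protocol, direction, bs, J, t_final)

    lo = 0.0
    hi = 5.0
    while outcome(hi) not in _PROPAGATING:
        hi *= 2.0
        if hi > tau_cap:
            raise RuntimeError(f"no propagation for any tested tau <= {tau_cap}")
    while hi - lo > 2 * tol:
        mid = 0.5 * (lo + hi)
        if outcome(mid) in _PROPAGATING:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(
        kind="tau_star", value=0.5 * (lo + hi), bracket=(lo, hi), tol=tol,
        direction=direction, params=vars(params),
    )


def find_pinning_boundary(
    params_base: ModelParams,
    free: str,
    direction: str,
    bracket: Optional[tuple[float, float]] = None,
    tol: float = BOUNDARY_TOL,
    speed_kwargs: Optional[dict] = None,
) -> ThresholdResult:
    """Boundary of the pinning region in one free parameter (q or theta).

    Bottom-up: smallest value at which c_{u->d} vanishes (the propagating side
    has c_{u->d} > 0).  Top-down: the analogous boundary for c_{d->u} < 0 —
    for free q this is the *largest* q with c_{d->u} = 0 (propagating side
    above), for free theta the smallest theta with c_{d->u} = 0.
    """
    if free not in ("q", "theta"):
        raise ValueError("free parameter must be 'q' or 'theta'")
    kw = {**_SPEED_KW, **(speed_kwargs or {})}
    wave = "u_to_d" if direction == "bottom_up" else "d_to_u"

    def propagating(x: float) -> bool:
        p = {**vars(params_base), free: x}
        est = _robust_speed(ModelParams(**p), wave, kw)
        if est.pinned:
            return False
        return est.c > 0 if direction == "bottom_up" else est.c < 0

    if bracket is None:
        if free == "q":
            bracket = (0.02, 1.0 - params_base.p - 0.02)
        else:
            bs = equilibrium_branches(params_base.theta, params_base.mu)
            bracket = (bs.theta_star + 0.02, bs.theta_star_upper - 0.02)
    lo, hi = bracket
    p_lo, p_hi = propagating(lo), propagating(hi)
    if p_lo == p_hi:
        raise ValueError(
            f"no sign change in bracket {bracket}: propagating({lo})={p_lo}, "
            f"propagating({hi})={p_hi}"
        )
    while hi - lo > 2 * tol:
        mid = 0.5 * (lo + hi)
        if propagating(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(
        kind="q0" if free == "q" else "theta0",
        value=0.5 * (lo + hi), bracket=(lo, hi), tol=tol,
        direction=direction, params=vars(params_base),
    )


def regime_map(
    q_grid,
    s0_grid,
    theta: float,
    mu: float,
    p: float,
    J: int = CLASSIFY_J,
    t_final: float = CLASSIFY_T_FINAL,
) -> pd.DataFrame:
    """Joint bottom-up/top-down constant-input outcome per (q, s0) node.

    Labels: both_propagate (the normal working regime), bottom_up_only,
    top_down_only, both_stagnate; undetermined nodes are marked, not fatal.
    """
    rows = []
    for q in np.asarray(q_grid, dtype=float):
        try:
            params = ModelParams(theta=theta, mu=mu, p=p, q=q)
            bs = equilibrium_branches(theta, mu)
            if not bs.bistable:
                raise ValueError("outside bistable window")
        except ValueError:
            for s0 in np.asarray(s0_grid, dtype=float):
                rows.append({"q": q, "s0": s0, "bottom_up": "inadmissible",
                             "top_down": "inadmissible", "label": "inadmissible"})
            continue
        for s0 in np.asarray(s0_grid, dtype=float):
            outcomes = {}
            for direction in ("bottom_up", "top_down"):
                try:
                    protocol = InputProtocol.constant(s0, baseline=bs.x_d)
                    outcomes[direction] = _classify_run(
                        params, protocol, direction, bs, J, t_final
                    )
                except (UndeterminedOutcomeError, ValueError):
                    outcomes[direction] = "undetermined"
            bu = outcomes["bottom_up"] == "front_propagation"
            td = outcomes["top_down"] == "front_propagation"
            if "undetermined" in outcomes.values():
                label = "undetermined"
            elif bu and td:
                label = "both_propagate"
            elif bu:
                label = "bottom_up_only"
            elif td:
                label = "top_down_only"
            else:
                label = "both_stagnate"
            rows.append({"q": q, "s0": s0, "bottom_up": outcomes["bottom_up"],
                         "top_down": outcomes["top_down"], "label": label})
    return pd.DataFrame(rows, columns=["q", "s0", "bottom_up", "top_down", "label"])
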