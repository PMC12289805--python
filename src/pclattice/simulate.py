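"""Time integration, input protocols, initial conditions, and presets.

Layer-index convention: the input layer is lattice index 0.  Bottom-up
(semi-infinite) states store layers 1..J at array positions 0..J-1; top-down
states store layers -1..-J at array positions 0..J-1 (array position = distance
from the input layer minus one); truncated bi-infinite states carry an
``offset`` so that lattice index = offset + array position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import BranchSet, ModelParams, equilibrium_branches
from .lattice_model import bi_infinite_rhs, scalar_rhs
from .nonlinearity import sigmoid, sigmoid_deriv

__all__ = [
    "InputProtocol",
    "StepInitialCondition",
    "Trajectory",
    "make_initial",
    "integrate",
    "run_scenario",
    "scenario_presets",
    "top_down_rhs",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_T_FINAL = 200.0
DEFAULT_OUTPUT_DT = 0.5
DEFAULT_J = 400


@dataclass(frozen=True)
class InputProtocol:
    """Input presented at layer 0.

    ``constant``: s0 for all t.  ``flashed``: s0 on [0, tau], then the
    baseline (default: the down state).  ``none``: no input layer (bi-infinite
    runs).
    """

    kind: str
    s0: Optional[float] = None
    tau: Optional[float] = None
    baseline: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "constant", "flashed"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "constant":
            if self.s0 is None or not np.isfinite(self.s0):
                raise ValueError("constant protocol requires finite s0")
            if self.baseline is not None and self.s0 < self.baseline:
                raise ValueError("constant protocol requires s0 >= baseline (down state)")
        if self.kind == "flashed":
            if self.tau is None or self.tau <= 0:
                raise ValueError("flashed protocol requires tau > 0")
            if self.s0 is None or self.baseline is None or self.s0 <= self.baseline:
                raise ValueError("flashed protocol requires s0 > baseline")

    @classmethod
    def none(cls) -> "InputProtocol":
        return cls(kind="none")

    @classmethod
    def constant(cls, s0: float, baseline: Optional[float] = None) -> "InputProtocol":
        return cls(kind="constant", s0=s0, baseline=baseline)

    @classmethod
    def flashed(cls, s0: float, tau: float, baseline: float) -> "InputProtocol":
        return cls(kind="flashed", s0=s0, tau=tau, baseline=baseline)

    def value(self, t: float) -> float:
        if self.kind == "constant":
            return self.s0
        if self.kind == "flashed":
            return self.s0 if t <= self.tau else self.baseline
        raise RuntimeError("protocol 'none' has no input value")

    def breakpoints(self) -> tuple[float, ...]:
        """Times where the input is discontinuous (integration is split there)."""
        return (self.tau,) if self.kind == "flashed" else ()

    def to_dict(self) -> dict:
        return {"kind": self.kind, "s0": self.s0, "tau": self.tau, "baseline": self.baseline}


@dataclass(frozen=True)
class StepInitialCondition:
    """Step profile between the two stable states (or a homogeneous state).

    ``interface_index`` is the last lattice index carrying the left state; it
    must sit at least ``margin`` layers from both ends of the truncation.
    """

    direction: str
    interface_index: int = 0
    margin: int = 20

    def __post_init__(self) -> None:
        if self.direction not in ("u_to_d", "d_to_u", "all_down", "all_up"):
            raise ValueError(f"unknown initial-condition direction {self.direction!r}")


def make_initial(
    spec: StepInitialCondition, branch_set: BranchSet, J: int, offset: int = 0
) -> np.ndarray:
    """Build the J-layer initial vector; lattice index = offset + array index."""
    if not branch_set.bistable:
        raise ValueError("step initial data requires a bistable branch set")
    x_d, x_u = branch_set.x_d, branch_set.x_u
    if spec.direction == "all_down":
        return np.full(J, x_d)
    if spec.direction == "all_up":
        return np.full(J, x_u)
    lo, hi = offset, offset + J - 1
    if not (lo + spec.margin <= spec.interface_index <= hi - spec.margin):
        raise ValueError(
            f"interface index {spec.interface_index} closer than {spec.margin} "
            f"layers to the truncation boundary [{lo}, {hi}]"
        )
    j = offset + np.arange(J)
    if spec.direction == "u_to_d":
        return np.where(j <= spec.interface_index, x_u, x_d)
    return np.where(j <= spec.interface_index, x_d, x_u)


@dataclass
class Trajectory:
    """Time-indexed layer activities plus run metadata.

    ``values`` has shape (J, n_times); column k is the state at ``times[k]``.
    """

    times: np.ndarray
    values: np.ndarray
    params: Optional[ModelParams] = None
    protocol: Optional[InputProtocol] = None
    truncation: dict = field(default_factory=dict)
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("output times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory contains non-finite values")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def final_state(self) -> np.ndarray:
        return self.values[:, -1]

    def snapshot(self, k: int) -> np.ndarray:
        return self.values[:, k]

    def lattice_indices(self) -> np.ndarray:
        if self.truncation.get("geometry") == "top_down":
            return -(np.arange(self.n_layers) + 1)
        offset = self.truncation.get("offset", 0)
        return offset + np.arange(self.n_layers)

    def to_csv(self, path) -> None:
        """Wide CSV: column 0 time, one column per layer (lattice index header)."""
        header = "time," + ",".join(f"layer_{j}" for j in self.lattice_indices())
        data = np.column_stack([self.times, self.values.T])
        np.savetxt(path, data, delimiter=",", header=header, comments="")

    def to_npz(self, path) -> None:
        """Compressed binary container; metadata goes in a JSON sidecar."""
        np.savez_compressed(path, times=self.times, values=self.values)
        sidecar = str(path) + ".json" if not str(path).endswith(".npz") \
            else str(path)[:-4] + ".json"
        with open(sidecar, "w") as fh:
            json.dump(self.meta_dict(), fh, indent=2, default=str)

    def meta_dict(self) -> dict:
        return {
            "params": None if self.params is None else vars(self.params),
            "protocol": None if self.protocol is None else self.protocol.to_dict(),
            "truncation": self.truncation,
            "solver_meta": self.solver_meta,
        }


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    initial: np.ndarray,
    t_final: float,
    output_dt: float = DEFAULT_OUTPUT_DT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
    breakpoints: tuple[float, ...] = (),
    params: Optional[ModelParams] = None,
    protocol: Optional[InputProtocol] = None,
    truncation: Optional[dict] = None,
) -> Trajectory:
    """Adaptive integration of ``y' = rhs(t, y)`` sampled every ``output_dt``.

    Integration is split at ``breakpoints`` (input discontinuities) so the
    adaptive controller never steps across a jump.  Deterministic for fixed
    inputs and tolerances.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    y0 = np.asarray(initial, dtype=float)
    t_out = np.arange(0.0, t_final + output_dt / 2, output_dt)
    edges = [0.0] + sorted(b for b in breakpoints if 0.0 < b < t_final) + [t_final]

    times = [np.array([0.0])]
    states = [y0[:, None]]
    nfev = 0
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = t_out[(t_out > a) & (t_out <= b)]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            t_eval=np.unique(np.append(t_eval, b)),
            rtol=rtol,
            atol=atol,
            method=method,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed at t={sol.t[-1] if sol.t.size else a}: {sol.message}"
            )
        nfev += sol.nfev
        keep = np.isin(sol.t, t_eval)
        times.append(sol.t[keep])
        states.append(sol.y[:, keep])
        y = sol.y[:, -1]

    return Trajectory(
        times=np.concatenate(times),
        values=np.concatenate(states, axis=1),
        params=params,
        protocol=protocol,
        truncation=truncation or {},
        solver_meta={"rtol": rtol, "atol": atol, "method": method, "nfev": nfev},
    )


def top_down_rhs(state: np.ndarray, t: float, protocol, params: ModelParams,
                 tail: float) -> np.ndarray:
    """Top-down semi-infinite truncation: layers -1..-J at array index 0..J-1.

    The input layer (lattice 0) is the *feedback* neighbor of array index 0;
    the far-end feedforward ghost (layer -J-1) is clamped to the asymptotic
    tail equilibrium ``tail``.
    """
    v = np.asarray(state, dtype=float)
    J = v.shape[0]
    if J < 2:
        raise ValueError("at least 2 layers required")
    sg = params.sigmoid
    s0 = float(protocol.value(t) if hasattr(protocol, "value") else protocol(t))

    u = np.empty(J)  # feedforward neighbor v_{j-1} (deeper into the network)
    u[:-1] = v[1:]
    u[-1] = tail
    w = np.empty(J)  # feedback neighbor v_{j+1} (toward the input layer)
    w[0] = s0
    w[1:] = v[:-1]

    sv = sigmoid(v, sg)
    return (
        (1.0 - params.p - params.q) * (sigmoid(u, sg) - v)
        + params.p * sigmoid_deriv(v, sg) * (u - sv)
        + params.q * (sigmoid(w, sg) - v)
    )


# --------------------------------------------------------------------------
# Scenario presets (parameters from the figure captions; where a caption only
# states the speed-ordering regime, the preset uses a parameter point verified
# to realize that regime).

def _preset(theta, mu, p, q, geometry, protocol_kind, J, t_final, **kw):
    return dict(theta=theta, mu=mu, p=p, q=q, geometry=geometry,
                protocol=protocol_kind, J=J, t_final=t_final, **kw)


scenario_presets: dict[str, dict] = {
    # bi-infinite step-initial-data wave runs
    "fig2a": _preset(0.5, 16, 0.1, 0.6, "bi_infinite", "none", 400, 200.0,
                     initial="u_to_d"),
    "fig2c": _preset(0.5, 16, 0.1, 0.4, "bi_infinite", "none", 400, 200.0,
                     initial="u_to_d"),
    "fig2d": _preset(0.5, 16, 0.1, 0.6, "bi_infinite", "none", 400, 200.0,
                     initial="d_to_u"),
    "fig2f": _preset(0.5, 16, 0.1, 0.4, "bi_infinite", "none", 400, 200.0,
                     initial="d_to_u"),
    # bottom-up constant input: stagnation (a) vs propagation (b)
    "fig6a": _preset(0.35, 16, 0.1, 0.35, "bottom_up", "constant", 100, 200.0,
                     s0=0.30),
    "fig6b": _preset(0.35, 16, 0.1, 0.35, "bottom_up", "constant", 100, 200.0,
                     s0=0.60),
    # bottom-up flashed input, cases (i)-(iii)
    "fig9a": _preset(0.55, 16, 0.1, 0.3, "bottom_up", "flashed", 100, 150.0,
                     tau=20.0),
    "fig9b": _preset(0.45, 16, 0.1, 0.3, "bottom_up", "flashed", 100, 150.0,
                     tau=20.0),
    "fig9c": _preset(0.35, 16, 0.1, 0.5, "bottom_up", "flashed", 100, 250.0,
                     tau=20.0),
    # bottom-up flashed, equal positive speeds: traveling pulse
    "fig10": _preset(0.5, 16, 0.1, 0.3, "bottom_up", "flashed", 100, 150.0,
                     tau=25.0),
    # top-down constant input: stagnation (a) vs propagation (b)
    "fig12a": _preset(0.35, 16, 0.1, 0.65, "top_down", "constant", 100, 200.0,
                      s0=0.30),
    "fig12b": _preset(0.35, 16, 0.1, 0.65, "top_down", "constant", 100, 200.0,
                      s0=0.60),
    # top-down flashed input, cases (i)-(iii)
    "fig15a": _preset(0.55, 16, 0.1, 0.7, "top_down", "flashed", 100, 150.0,
                      tau=20.0),
    "fig15b": _preset(0.45, 16, 0.1, 0.7, "top_down", "flashed", 100, 180.0,
                      tau=20.0),
    "fig15c": _preset(0.35, 16, 0.1, 0.5, "top_down", "flashed", 100, 250.0,
                      tau=20.0),
}


def run_scenario(preset_name: str, **overrides) -> Trajectory:
    """Integrate one of the named scenario presets and return its trajectory."""
    if preset_name not in scenario_presets:
        raise KeyError(
            f"unknown preset {preset_name!r}; available: "
            + ", ".join(sorted(scenario_presets))
        )
    cfg = {**scenario_presets[preset_name], **overrides}
    params = ModelParams(theta=cfg["theta"], mu=cfg["mu"], p=cfg["p"], q=cfg["q"])
    bs = equilibrium_branches(params.theta, params.mu)
    J, t_final = cfg["J"], cfg["t_final"]

    if cfg["protocol"] == "none":
        protocol = InputProtocol.none()
    elif cfg["protocol"] == "constant":
        protocol = InputProtocol.constant(cfg["s0"], baseline=bs.x_d)
    else:
        protocol = InputProtocol.flashed(
            cfg.get("s0", bs.x_u), cfg["tau"], baseline=bs.x_d
        )

    if cfg["geometry"] == "bi_infinite":
        offset = -(J // 2)
        init = make_initial(
            StepInitialCondition(cfg["initial"], interface_index=0), bs, J, offset
        )
        left = init[0]
        right = init[-1]
        rhs = lambda t, y: bi_infinite_rhs(y, t, params, left, right)
        truncation = {"J": J, "offset": offset, "boundary": "clamped", "geometry": "bi_infinite"}
    elif cfg["geometry"] == "bottom_up":
        init = make_initial(StepInitialCondition("all_down"), bs, J)
        rhs = lambda t, y: scalar_rhs(y, t, protocol, params)
        truncation = {"J": J, "offset": 1, "boundary": "sigmoid_inverse", "geometry": "bottom_up"}
    else:  # top_down
        init = make_initial(StepInitialCondition("all_down"), bs, J)
        rhs = lambda t, y: top_down_rhs(y, t, protocol, params, tail=bs.x_d)
        truncation = {"J": J, "offset": -1, "boundary": "clamped_tail",
                      "geometry": "top_down", "tail": bs.x_d}

    return integrate(
        rhs,
        init,
        t_final,
        breakpoints=protocol.breakpoints() if cfg["protocol"] != "none" else (),
        params=params,
        protocol=protocol,
        truncation=truncation,
    )
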