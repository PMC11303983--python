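"""Time integration and the stepwise stable-state-finding protocol.

The protocol holds the environmental drivers fixed for a long equilibration
window (1e6 h of biological time by default) at each point of a gradient,
records the end-of-window state, then moves the drivers one step and continues
from the recorded state.  Running the gradient independently in both
directions from the same initial state exposes hysteresis: over the bistable
range the two runs settle on different attractors.

To keep either functional group from being lost to numerical underflow, a
fixed immigration impulse (1 cell L^-1 per group by default) is injected every
1000 h; integration restarts at these impulse boundaries, so the ODE solver
only ever sees the smooth flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .environment import Direction, DriverSequence, EnvironmentalAsymmetry, make_driver_sequence
from .model import ModelParameters, SystemState, _rhs

__all__ = [
    "SimulationSettings",
    "SimulationError",
    "StepResult",
    "DirectionRun",
    "HysteresisResult",
    "Trajectory",
    "integrate_step",
    "run_direction",
    "run_hysteresis",
    "run_temporal",
]

log = logging.getLogger("symtip")

_VARS = ("N_CB", "N_SB", "O", "S", "P")


class SimulationError(RuntimeError):
    """Integrator failure or non-finite state, with failure context attached."""

    def __init__(self, message: str, *, time: float | None = None,
                 state: np.ndarray | None = None, step_index: int | None = None,
                 direction: Direction | None = None):
        super().__init__(message)
        self.time = time
        self.state = state
        self.step_index = step_index
        self.direction = direction


def _default_initial_state() -> SystemState:
    # 1e5 cells/L per group, 20 μM of each substrate, 10 μM phosphorus
    return SystemState(1e5, 1e5, 20.0, 20.0, 10.0)


@dataclass(frozen=True)
class SimulationSettings:
    """Protocol and solver configuration.

    ``step_duration`` is the biological time spent at each gradient step and
    must be a positive multiple of ``immigration_interval``.  Absolute solver
    tolerances are split by variable kind because cell densities span ~10
    orders of magnitude while concentrations stay within ~1e-1..1e2 μM.

    The convergence-gated early exit (``early_exit=True``) ends a step once
    the weighted residual ``max |dx/dt| / (1 + |x|)`` stays below
    ``early_exit_residual`` for ``early_exit_consecutive`` consecutive
    immigration chunks.  It is off by default: the plain protocol integrates
    the full ``step_duration`` regardless.
    """

    step_duration: float = 1_000_000.0
    immigration_interval: float = 1000.0
    immigration_amount: float = 1.0
    initial_state: SystemState = field(default_factory=_default_initial_state)
    solver_rel_tol: float = 1e-8
    solver_abs_tol_cells: float = 1e-10
    solver_abs_tol_conc: float = 1e-10
    steady_state_residual_tol: float = 1e-3
    early_exit: bool = False
    early_exit_residual: float = 1e-7
    early_exit_consecutive: int = 10
    solver_method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.step_duration <= 0 or self.immigration_interval <= 0:
            raise ValueError("durations must be positive")
        n = self.step_duration / self.immigration_interval
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                "step_duration must be a positive multiple of immigration_interval"
            )
        for name in ("solver_rel_tol", "solver_abs_tol_cells", "solver_abs_tol_conc",
                     "steady_state_residual_tol", "early_exit_residual"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.immigration_amount < 0:
            raise ValueError("immigration_amount must be >= 0")

    @property
    def n_chunks(self) -> int:
        return int(round(self.step_duration / self.immigration_interval))

    @property
    def abs_tol(self) -> np.ndarray:
        return np.array(
            [self.solver_abs_tol_cells] * 2 + [self.solver_abs_tol_conc] * 3
        )

    def replace(self, **kwargs) -> "SimulationSettings":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StepResult:
    """End state of one gradient step plus convergence diagnostics."""

    state: SystemState
    residual: float          # weighted derivative norm at step end
    n_chunks: int            # immigration chunks actually integrated
    n_negative_clips: int    # chunks where a component was floored at zero


def _residual(y: np.ndarray, params: ModelParameters, a_O: float, a_S: float) -> float:
    d = _rhs(y, params, a_O, a_S)
    return float(np.max(np.abs(d) / (1.0 + np.abs(y))))


def _integrate_chunk(
    y: np.ndarray,
    params: ModelParameters,
    a_O: float,
    a_S: float,
    t0: float,
    t1: float,
    settings: SimulationSettings,
    t_eval: np.ndarray | None = None,
):
    p, aO, aS = params, a_O, a_S
    g_max, k_P, H_S, H_O = p.g_max, p.k_P, p.H_S, p.H_O
    y_P, p_O, p_S, m, c = p.y_P, p.p_O, p.p_S, p.m, p.c
    alpha_P, O_b, S_b, P_b = p.alpha_P, p.O_b, p.S_b, p.P_b

    def rhs(t, x):
        N_CB, N_SB, O, S, P = x
        g = g_max * P / (k_P + P)
        gCB = g * N_CB / (1.0 + S / H_S)
        gSB = g * N_SB / (1.0 + O / H_O)
        oxid = c * (O * S)  # grouped so the mirror swap is bitwise-exact
        return (
            gCB - m * N_CB,
            gSB - m * N_SB,
            p_O * gCB - oxid + aO * (O_b - O),
            p_S * gSB - oxid + aS * (S_b - S),
            -(gCB + gSB) / y_P + alpha_P * (P_b - P),
        )

    sol = solve_ivp(
        rhs, (t0, t1), y, method=settings.solver_method,
        rtol=settings.solver_rel_tol, atol=settings.abs_tol, t_eval=t_eval,
    )
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        raise SimulationError(
            f"integration failed at t={sol.t[-1]:.6g} h: {sol.message}",
            time=float(sol.t[-1]), state=sol.y[:, -1],
        )
    return sol


def integrate_step(
    state0: SystemState,
    params: ModelParameters,
    a_O: float,
    a_S: float,
    settings: SimulationSettings,
) -> StepResult:
    """Hold drivers fixed for one protocol step and return the final state.

    The step is integrated in immigration chunks: at the start of every chunk
    ``immigration_amount`` cells L^-1 are added to both groups, then the smooth
    flow is integrated over ``immigration_interval``.  Any component driven
    (marginally) negative by the solver is floored at zero and counted.  The
    returned residual is evaluated on the final state *before* any further
    immigration impulse.
    """
    if a_O < 0 or a_S < 0:
        raise ValueError("diffusivities must be >= 0")
    y = state0.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite initial state")
    dt = settings.immigration_interval
    res = _residual(y, params, a_O, a_S)
    consec = 0
    n_clips = 0
    n_done = 0
    for k in range(settings.n_chunks):
        y[0] += settings.immigration_amount
        y[1] += settings.immigration_amount
        try:
            sol = _integrate_chunk(y, params, a_O, a_S, 0.0, dt, settings)
        except SimulationError as err:
            err.time = (err.time or 0.0) + k * dt
            raise
        y = sol.y[:, -1].copy()
        if np.any(y < 0):
            if np.any(y < -1e-9):
                n_clips += 1
            y[y < 0] = 0.0
        n_done = k + 1
        res = _residual(y, params, a_O, a_S)
        if settings.early_exit:
            consec = consec + 1 if res < settings.early_exit_residual else 0
            if consec >= settings.early_exit_consecutive:
                break
    if res > settings.steady_state_residual_tol:
        log.warning(
            "step did not reach steady state: residual %.3g at a_O=%.4g a_S=%.4g",
            res, a_O, a_S,
        )
    return StepResult(SystemState.from_array(y), res, n_done, n_clips)


@dataclass(frozen=True)
class DirectionRun:
    """End-of-step states recorded along one direction of the gradient."""

    drivers: DriverSequence
    states: tuple[SystemState, ...]
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if len(self.states) != len(self.drivers):
            raise ValueError("states and drivers must align")

    def substrate(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.states])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "direction": self.drivers.direction.value,
                "step_index": np.arange(len(self.states)),
                "a_O": self.drivers.a_O,
                "a_S": self.drivers.a_S,
            }
        )
        for i, v in enumerate(_VARS):
            df[v] = [s.as_array()[i] for s in self.states]
        df["residual"] = self.residuals
        return df


ProgressCallback = Callable[[int, float, float, StepResult], None]


def run_direction(
    params: ModelParameters,
    drivers: DriverSequence,
    settings: SimulationSettings,
    progress: ProgressCallback | None = None,
) -> DirectionRun:
    """Execute the stepwise protocol along one driver sequence.

    Starts from ``settings.initial_state``; each gradient step continues from
    the previous step's final state.
    """
    state = settings.initial_state
    states: list[SystemState] = []
    residuals: list[float] = []
    for i, (a_O, a_S) in enumerate(zip(drivers.a_O, drivers.a_S)):
        try:
            step = integrate_step(state, params, float(a_O), float(a_S), settings)
        except SimulationError as err:
            err.step_index = i
            err.direction = drivers.direction
            raise
        state = step.state
        states.append(state)
        residuals.append(step.residual)
        log.debug(
            "step %d/%d a_O=%.4g a_S=%.4g residual=%.3g chunks=%d",
            i + 1, len(drivers), a_O, a_S, step.residual, step.n_chunks,
        )
        if progress is not None:
            progress(i, float(a_O), float(a_S), step)
    return DirectionRun(drivers, tuple(states), np.array(residuals))


@dataclass(frozen=True)
class HysteresisResult:
    """Stable states along the gradient for both directions of change."""

    toward_oxic: DirectionRun
    toward_anoxic: DirectionRun

    @property
    def states_toward_oxic(self) -> tuple[SystemState, ...]:
        return self.toward_oxic.states

    @property
    def states_toward_anoxic(self) -> tuple[SystemState, ...]:
        return self.toward_anoxic.states

    def to_dataframe(self) -> pd.DataFrame:
        return pd.concat(
            [self.toward_oxic.to_dataframe(), self.toward_anoxic.to_dataframe()],
            ignore_index=True,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_hysteresis(
    params: ModelParameters,
    asymmetry: EnvironmentalAsymmetry | float = 1.0,
    settings: SimulationSettings | None = None,
    n_steps: int = 101,
    progress: ProgressCallback | None = None,
) -> HysteresisResult:
    """Two independent stepwise runs, one per direction of environmental change.

    Both runs start from the same initial state; the long equilibration at the
    first gradient step establishes the attractor appropriate to that end of
    the gradient.
    """
    settings = settings or SimulationSettings()
    runs = {}
    for direction in (Direction.TOWARD_OXIC, Direction.TOWARD_ANOXIC):
        drivers = make_driver_sequence(n_steps, asymmetry, direction)
        log.info("hysteresis: running %s (%d steps)", direction.value, n_steps)
        runs[direction] = run_direction(params, drivers, settings, progress)
    return HysteresisResult(runs[Direction.TOWARD_OXIC], runs[Direction.TOWARD_ANOXIC])


@dataclass(frozen=True)
class Trajectory:
    """Recorded time series of the full state during a temporal simulation."""

    time_h: np.ndarray
    states: np.ndarray          # shape (n_times, 5), column order _VARS
    a_O: np.ndarray
    a_S: np.ndarray

    def __len__(self) -> int:
        return len(self.time_h)

    def column(self, name: str) -> np.ndarray:
        return self.states[:, _VARS.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.time_h, "a_O": self.a_O, "a_S": self.a_S})
        for i, v in enumerate(_VARS):
            df[v] = self.states[:, i] if len(self) else np.array([])
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_temporal(
    params: ModelParameters,
    pattern: DriverSequence,
    settings: SimulationSettings | None = None,
    record_every: float = 200.0,
) -> Trajectory:
    """Integrate continuously across a time-indexed driver schedule.

    The drivers are piecewise constant between the schedule's time stamps;
    immigration impulses continue at their fixed cadence throughout.  The
    state is recorded every ``record_every`` hours (plus at every chunk end),
    which resolves the fast transients at the regime shifts.
    """
    settings = settings or SimulationSettings()
    if len(pattern) == 0:
        empty = np.array([])
        return Trajectory(empty, np.empty((0, 5)), empty.copy(), empty.copy())
    if pattern.time_h is None:
        raise ValueError("run_temporal requires a time-indexed schedule")
    if record_every <= 0:
        raise ValueError("record_every must be > 0")
    seg_starts = pattern.time_h
    t_end = pattern.t_end
    if t_end is None:
        spacing = np.diff(seg_starts).mean() if len(seg_starts) > 1 else settings.immigration_interval
        t_end = float(seg_starts[-1] + spacing)
    seg_bounds = np.append(seg_starts, t_end)

    y = settings.initial_state.as_array()
    dt = settings.immigration_interval
    times: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    aOs: list[np.ndarray] = []
    aSs: list[np.ndarray] = []
    for i in range(len(pattern)):
        a_O, a_S = float(pattern.a_O[i]), float(pattern.a_S[i])
        t0, t1 = float(seg_bounds[i]), float(seg_bounds[i + 1])
        t = t0
        while t < t1 - 1e-9:
            tc = min(t + dt, t1)
            y[0] += settings.immigration_amount
            y[1] += settings.immigration_amount
            n_rec = max(int(np.ceil((tc - t) / record_every)), 1)
            t_eval = np.linspace(t, tc, n_rec + 1)[1:]
            try:
                sol = _integrate_chunk(y, params, a_O, a_S, t, tc, settings, t_eval=t_eval)
            except SimulationError as err:
                err.step_index = i
                raise
            y = sol.y[:, -1].copy()
            y[y < 0] = 0.0
            times.append(sol.t)
            ys.append(sol.y.T)
            aOs.append(np.full(len(sol.t), a_O))
            aSs.append(np.full(len(sol.t), a_S))
            t = tc
        log.debug("temporal segment %d/%d done (t=%.4g h)", i + 1, len(pattern), t)
    return Trajectory(
        np.concatenate(times),
        np.vstack(ys),
        np.concatenate(aOs),
        np.concatenate(aSs),
    )
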