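"""Fixed-step integration of the replicator ODE with policy interventions.

The reference system-dynamics runs use a fixed step of 0.05 over the
interval [0, 15] with a forward-Euler update; that is the default here, and
a classical Runge-Kutta 4 step is available for cross-validation.  States
are clamped to the unit cube after every step, and a schedule of mid-run
interventions (set a coordinate once, or clamp it for the rest of the run)
models policy changes such as cancelling regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .game_model import AS_PRINTED, VARIANTS, ParameterSet, StrategyState, replicator_field

__all__ = [
    "EULER",
    "RK4",
    "METHODS",
    "SimulationSettings",
    "InterventionEvent",
    "InterventionSchedule",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "detect_convergence",
    "peak_time",
    "CORNERS",
]

EULER = "euler"
RK4 = "rk4"
METHODS = (EULER, RK4)

#: The 8 corner states of the unit cube (absorbing fixed points).
CORNERS: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
    (1.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.0, 1.0, 1.0), (1.0, 1.0, 1.0),
)

_COORD_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class SimulationSettings:
    """Integration window, step size, method and enterprise-rate variant."""

    t_initial: float = 0.0
    t_final: float = 15.0
    dt: float = 0.05
    method: str = EULER
    variant: str = AS_PRINTED

    def __post_init__(self) -> None:
        if self.t_final <= self.t_initial:
            raise ValueError("t_final must exceed t_initial")
        if not 0.0 < self.dt <= self.t_final - self.t_initial:
            raise ValueError("dt must satisfy 0 < dt <= t_final - t_initial")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_final - self.t_initial) / self.dt))


class InterventionEvent(NamedTuple):
    """One scheduled policy event.

    ``action="set_value"`` sets the coordinate once at the first step
    boundary at or after ``time``; ``action="clamp"`` sets it and holds it
    fixed for the remainder of the run.
    """

    time: float
    coordinate: str  # "x", "y" or "z"
    action: str      # "set_value" or "clamp"
    value: float


@dataclass(frozen=True)
class InterventionSchedule:
    events: tuple[InterventionEvent, ...] = ()

    def __init__(self, events: Sequence[InterventionEvent] = ()):
        object.__setattr__(self, "events", tuple(events))
        for ev in self.events:
            if ev.coordinate not in _COORD_INDEX:
                raise ValueError(f"unknown coordinate {ev.coordinate!r}")
            if ev.action not in ("set_value", "clamp"):
                raise ValueError(f"unknown action {ev.action!r}")
            if not 0.0 <= ev.value <= 1.0:
                raise ValueError(f"event value {ev.value} outside [0, 1]")

    def __bool__(self) -> bool:
        return bool(self.events)


@dataclass(frozen=True)
class Trajectory:
    """Time series of the strategy state from a fixed-step run."""

    times: np.ndarray                 # shape (n+1,)
    states: np.ndarray                # shape (n+1, 3), columns x, y, z
    settings: SimulationSettings
    interventions: InterventionSchedule

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_state(self) -> StrategyState:
        return StrategyState(*self.states[-1])

    def coordinate(self, name: str) -> np.ndarray:
        return self.states[:, _COORD_INDEX[name]]

    def to_csv(self, path: str | Path) -> None:
        """Write ``time,x,y,z`` rows at full float precision."""
        lines = ["time,x,y,z"]
        for t, (x, y, z) in zip(self.times, self.states):
            lines.append(f"{float(t)!r},{float(x)!r},{float(y)!r},{float(z)!r}")
        Path(path).write_text("\n".join(lines) + "\n")


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(f"non-finite state at step {step} (t = {time:g})")


def _rhs(params: ParameterSet, s: np.ndarray, variant: str) -> np.ndarray:
    state = StrategyState(*np.clip(s, 0.0, 1.0))
    return np.asarray(replicator_field(params, state, variant))


def integrate(
    params: ParameterSet,
    initial: StrategyState,
    settings: SimulationSettings | None = None,
    schedule: InterventionSchedule | None = None,
) -> Trajectory:
    """Integrate the replicator field from ``initial`` under ``settings``.

    The run is fully deterministic.  After every step the state is clamped
    to the unit cube; scheduled events fire at the first step boundary at or
    after their event time; clamped coordinates stay at their event value.
    """
    settings = settings or SimulationSettings()
    schedule = schedule or InterventionSchedule()
    for ev in schedule.events:
        if not settings.t_initial <= ev.time <= settings.t_final:
            raise ValueError(
                f"event time {ev.time} outside [{settings.t_initial}, {settings.t_final}]"
            )
    n = settings.n_steps
    dt = settings.dt
    times = settings.t_initial + dt * np.arange(n + 1)
    states = np.empty((n + 1, 3))
    s = np.array(initial.as_tuple(), dtype=float)
    events = sorted(schedule.events, key=lambda ev: ev.time)
    clamped: dict[int, float] = {}
    next_event = 0

    for k in range(n + 1):
        # fire events whose time has been reached (tolerate step-boundary fp noise)
        while next_event < len(events) and events[next_event].time <= times[k] + 1e-9 * dt:
            ev = events[next_event]
            idx = _COORD_INDEX[ev.coordinate]
            s[idx] = ev.value
            if ev.action == "clamp":
                clamped[idx] = ev.value
            next_event += 1
        states[k] = s
        if k == n:
            break
        if settings.method == EULER:
            s = s + dt * _rhs(params, s, settings.variant)
        else:
            k1 = _rhs(params, s, settings.variant)
            k2 = _rhs(params, s + 0.5 * dt * k1, settings.variant)
            k3 = _rhs(params, s + 0.5 * dt * k2, settings.variant)
            k4 = _rhs(params, s + dt * k3, settings.variant)
            s = s + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(s)):
            raise IntegrationError(k + 1, float(times[k + 1]))
        np.clip(s, 0.0, 1.0, out=s)
        for idx, value in clamped.items():
            s[idx] = value

    return Trajectory(times, states, settings, schedule)


def detect_convergence(
    traj: Trajectory, tol: float = 0.01, dwell: int = 20
) -> StrategyState | None:
    """Corner the trajectory has settled on, or None.

    A corner qualifies when the max-coordinate distance from it stays below
    ``tol`` over the last ``dwell`` recorded states (all states if the
    trajectory is shorter than ``dwell``).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if tol <= 0.0:
        raise ValueError("tol must be positive")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    tail = traj.states[-dwell:]
    for corner in CORNERS:
        if np.max(np.abs(tail - np.asarray(corner))) < tol:
            return StrategyState(*corner)
    return None


def peak_time(traj: Trajectory, coordinate: str) -> tuple[float, float]:
    """Time and value of the first global maximum of one coordinate."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    series = traj.coordinate(coordinate)
    idx = int(np.argmax(series))
    return float(traj.times[idx]), float(series[idx])
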