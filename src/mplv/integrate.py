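"""Nonnegativity-preserving integration of the predator-prey/toxin system.

The model's constraint x1, x2, C1, C2 >= 0 is enforced by projecting the vector
field: while a component sits at zero and its raw rate is negative, that rate
is set to zero (the minimal rule that keeps trajectories in the nonnegative
orthant). The projected field is integrated with an adaptive explicit
Runge-Kutta 4(5) pair and reported on a dense, evenly spaced grid; sub-tolerance
negative excursions are clipped to zero after the fact. Crossings of the
effective-extinction threshold are recorded as events but never stop the run:
prey may keep rising after the predator is gone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelParameters, State, rhs

__all__ = [
    "SolverSettings",
    "EventRecord",
    "Trajectory",
    "IntegrationError",
    "project_rates",
    "simulate",
]

COMPONENTS = ("x1", "x2", "C1", "C2")


class IntegrationError(RuntimeError):
    """Integration failed; carries the last time reached by the solver."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time t={last_time:g})")
        self.last_time = last_time


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive RK45 settings and the reporting/extinction conventions.

    ``grid_dt`` is the dense-output spacing in months; ``extinction_threshold``
    is the density below which a population counts as effectively extinct.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    grid_dt: float = 1e-3
    extinction_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.grid_dt <= 0:
            raise ValueError("grid_dt must be positive")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be nonnegative")


@dataclass(frozen=True)
class EventRecord:
    component: str   # one of COMPONENTS
    time: float      # months
    kind: str        # e.g. "extinction_threshold"


@dataclass(frozen=True)
class Trajectory:
    """Dense solution of one run: time grid, states, settings and events."""

    t: np.ndarray                     # strictly increasing, months
    y: np.ndarray                     # shape (len(t), 4): x1, x2, C1, C2
    settings: SolverSettings
    events: tuple[EventRecord, ...] = field(default_factory=tuple)

    @property
    def x1(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def C1(self) -> np.ndarray:
        return self.y[:, 2]

    @property
    def C2(self) -> np.ndarray:
        return self.y[:, 3]

    def state(self, i: int) -> State:
        return State(float(self.t[i]), *map(float, self.y[i]))

    def __len__(self) -> int:
        return len(self.t)


def project_rates(y: np.ndarray, raw_rates: np.ndarray) -> np.ndarray:
    """Zero each rate whose component is at (or below) zero and decreasing."""
    y = np.asarray(y, dtype=float)
    raw = np.asarray(raw_rates, dtype=float)
    return np.where((y <= 0.0) & (raw < 0.0), 0.0, raw)


def _make_grid(t_end: float, dt: float) -> np.ndarray:
    n = int(round(t_end / dt))
    grid = np.linspace(0.0, n * dt, n + 1)
    if grid[-1] < t_end - 1e-12:
        grid = np.append(grid, t_end)
    else:
        grid[-1] = t_end
    return grid


def simulate(
    params: ModelParameters,
    init: State,
    t_end: float,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate the projected field from ``init`` to ``t_end`` months.

    Returns the trajectory sampled on the dense grid. An event is recorded the
    first time x1 or x2 falls below the extinction threshold; integration
    always continues to ``t_end``.
    """
    params.validate()
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    settings = settings or SolverSettings()

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return project_rates(y, rhs(t, y, params))

    grid = _make_grid(t_end, settings.grid_dt)
    sol = solve_ivp(
        f,
        (0.0, t_end),
        init.y,
        method="RK45",
        t_eval=grid,
        rtol=settings.rtol,
        atol=settings.atol,
        max_step=settings.max_step,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(sol.message, last)
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        bad = int(np.argmax(~np.all(np.isfinite(y), axis=1)))
        raise IntegrationError("non-finite state encountered", float(grid[max(bad - 1, 0)]))
    y = np.where(y < 0.0, 0.0, y)  # clip sub-tolerance negative excursions

    events = []
    eps = settings.extinction_threshold
    for j, name in enumerate(COMPONENTS[:2]):
        below = y[:, j] < eps
        if below.any() and not below[0]:
            i = int(np.argmax(below))
            events.append(EventRecord(name, float(grid[i]), "extinction_threshold"))
        elif below[0]:
            events.append(EventRecord(name, float(grid[0]), "extinction_threshold"))
    return Trajectory(t=grid, y=y, settings=settings, events=tuple(events))
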