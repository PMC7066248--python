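"""Trajectory summaries: oscillation extrema, period, extinction, outcome.

These are the quantities reported for each run: per-period peak and trough
lists for prey and predator, a peak-spacing period estimate, operational
extinction times (earliest time after which a density stays below a small
threshold), and a qualitative outcome label.

Outcome labelling. A continuum Lotka-Volterra population never reaches zero in
finite time, so "extinct" has two operational readings. A species whose
density falls below the threshold and stays there is extinct within the
window. A predator that has not yet crossed the threshold can still be on an
unambiguous path to extinction: its internal burden grows without bound, so
its oscillation troughs decay geometrically while the prey rebounds. The
classifier therefore also labels a run ``predator_extinct`` when the predator
trough envelope declines monotonically over at least three successive troughs
and loses more than 30% of its starting level within the window, while the
prey shows no such decline. The 30% cut separates genuine toxicity-driven
decay from the slow trough drift that weak burdens produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .integrate import Trajectory
from .model import ModelParameters, lv_invariant

__all__ = [
    "Extremum",
    "SummaryStats",
    "find_extrema",
    "estimate_period",
    "extinction_time",
    "classify_outcome",
    "invariant_drift",
    "summarize",
]

OUTCOMES = ("coexistence", "predator_extinct", "both_extinct")


@dataclass(frozen=True)
class Extremum:
    """One refined local extremum of a series."""

    time: float
    value: float
    series: str
    kind: str  # "max" or "min"


@dataclass(frozen=True)
class SummaryStats:
    """Headline quantities of one trajectory."""

    prey_extrema: tuple[Extremum, ...]
    predator_extrema: tuple[Extremum, ...]
    period: float | None                 # mean prey peak-to-peak spacing, months
    prey_extinction: float | None        # months, or None if never extinct
    predator_extinction: float | None
    outcome: str                         # one of OUTCOMES
    prey_range: tuple[float, float]      # (min, max) over the run
    predator_range: tuple[float, float]

    def peaks(self, series: str) -> list[Extremum]:
        src = self.prey_extrema if series == "x1" else self.predator_extrema
        return [e for e in src if e.kind == "max"]

    def troughs(self, series: str) -> list[Extremum]:
        src = self.prey_extrema if series == "x1" else self.predator_extrema
        return [e for e in src if e.kind == "min"]


def _refine(times: np.ndarray, values: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through the three samples bracketing index i."""
    if i == 0 or i == len(times) - 1:
        return float(times[i]), float(values[i])
    t0, t1, t2 = times[i - 1 : i + 2]
    v0, v1, v2 = values[i - 1 : i + 2]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (v1 - v0) + t1 * (v0 - v2) + t0 * (v2 - v1)) / denom
    if a == 0.0:
        return float(t1), float(v1)
    b = (t2**2 * (v0 - v1) + t1**2 * (v2 - v0) + t0**2 * (v1 - v2)) / denom
    c = v1 - a * t1**2 - b * t1
    tv = -b / (2 * a)
    if not (t0 <= tv <= t2):  # degenerate fit; keep the sample
        return float(t1), float(v1)
    return float(tv), float(a * tv**2 + b * tv + c)


def find_extrema(
    times,
    values,
    prominence_fraction: float = 0.01,
    series: str = "x1",
) -> list[Extremum]:
    """Local maxima and minima with prominence above a fraction of the range.

    Each extremum is refined by quadratic interpolation through the three
    bracketing samples, suppressing grid-discretisation error in both the time
    and the value.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if not (0 < prominence_fraction < 1):
        raise ValueError("prominence_fraction must lie in (0, 1)")
    rng = float(values.max() - values.min())
    if rng == 0.0:
        return []
    prom = prominence_fraction * rng
    out: list[Extremum] = []
    for sign, kind in ((1.0, "max"), (-1.0, "min")):
        idx, _ = find_peaks(sign * values, prominence=prom)
        for i in idx:
            t, v = _refine(times, values, int(i))
            out.append(Extremum(t, v, series, kind))
    out.sort(key=lambda e: e.time)
    return out


def estimate_period(extrema: list[Extremum]) -> float | None:
    """Mean spacing between consecutive maxima; None with fewer than two."""
    tmax = [e.time for e in extrema if e.kind == "max"]
    if len(tmax) < 2:
        return None
    return float(np.mean(np.diff(tmax)))


def extinction_time(times, values, threshold: float) -> float | None:
    """Earliest time after which the series stays below ``threshold``.

    The crossing is linearly interpolated between the bracketing samples.
    Returns None when the series ends at or above the threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values[-1] >= threshold:
        return None
    above = values >= threshold
    if not above.any():
        return float(times[0])
    i = int(len(values) - 1 - np.argmax(above[::-1]))  # last index at/above threshold
    t0, t1 = times[i], times[i + 1]
    v0, v1 = values[i], values[i + 1]
    if v0 == v1:
        return float(t1)
    return float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))


def _declining_troughs(troughs: list[Extremum], ratio: float) -> bool:
    """Monotone decline over >= 3 troughs losing more than (1 - ratio) overall."""
    if len(troughs) < 3:
        return False
    v = [e.value for e in troughs]
    return all(b < a for a, b in zip(v, v[1:])) and v[-1] < ratio * v[0]


def classify_outcome(
    prey_extinction: float | None,
    predator_extinction: float | None,
    prey_troughs: list[Extremum],
    predator_troughs: list[Extremum],
    decline_ratio: float = 0.7,
    prey_terminal_collapse: bool = False,
) -> str:
    """Qualitative fate of the run; see the module docstring for the rules.

    ``prey_terminal_collapse`` marks a prey series that, after the predator is
    gone, has fallen far below its own maximum and is still declining at the
    end of the window: with a monotonically growing internal burden that
    decline never reverses, so the run is a double collapse even though the
    prey has not yet crossed the threshold.
    """
    if prey_extinction is not None and predator_extinction is not None:
        return "both_extinct"
    if predator_extinction is not None:
        return "both_extinct" if prey_terminal_collapse else "predator_extinct"
    if prey_extinction is not None:
        # prey gone implies the predator starves; treat as both lost
        return "both_extinct"
    if _declining_troughs(predator_troughs, decline_ratio) and not _declining_troughs(
        prey_troughs, decline_ratio
    ):
        return "predator_extinct"
    return "coexistence"


def invariant_drift(traj: Trajectory, params: ModelParameters) -> float:
    """Relative drift of the toxin-free first integral H along a trajectory.

    Meaningful as an accuracy check only when r11 = r21 = 0 (H is conserved);
    otherwise it is a diagnostic of how strongly toxicity bends the orbit.
    The drift (max H - min H) is normalised by the depth of the initial orbit
    above H's global minimum at the fixed point; for a trajectory started at
    the fixed point (zero depth) the raw drift is returned.
    """
    x1, x2 = traj.x1, traj.x2
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("invariant_drift requires strictly positive densities")
    H = lv_invariant(x1, x2, params)
    x1s = params.r20 / params.conversion_eff
    x2s = params.prey_growth_eff / params.predation_eff
    depth = float(H[0] - lv_invariant(x1s, x2s, params))
    drift = float(H.max() - H.min())
    return drift / depth if depth > 0 else drift


def summarize(
    traj: Trajectory,
    prominence_fraction: float = 0.01,
    threshold: float | None = None,
) -> SummaryStats:
    """Compute all headline quantities for one trajectory."""
    eps = traj.settings.extinction_threshold if threshold is None else threshold
    prey = find_extrema(traj.t, traj.x1, prominence_fraction, series="x1")
    pred = find_extrema(traj.t, traj.x2, prominence_fraction, series="x2")
    t_prey = extinction_time(traj.t, traj.x1, eps)
    t_pred = extinction_time(traj.t, traj.x2, eps)
    # terminal collapse: well past the global maximum (more than e^2 below it)
    # and still strictly declining over the final half month of the run
    x1 = traj.x1
    tail = traj.t >= traj.t[-1] - 0.5
    collapsing = bool(
        x1[-1] < x1.max() * np.exp(-2.0)
        and x1[-1] > 0
        and np.all(np.diff(x1[tail]) <= 0)
    )
    outcome = classify_outcome(
        t_prey,
        t_pred,
        [e for e in prey if e.kind == "min"],
        [e for e in pred if e.kind == "min"],
        prey_terminal_collapse=collapsing,
    )
    return SummaryStats(
        prey_extrema=tuple(prey),
        predator_extrema=tuple(pred),
        period=estimate_period(prey),
        prey_extinction=t_prey,
        predator_extinction=t_pred,
        outcome=outcome,
        prey_range=(float(traj.x1.min()), float(traj.x1.max())),
        predator_range=(float(traj.x2.min()), float(traj.x2.max())),
    )
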