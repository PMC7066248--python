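"""Scenario registry: the study's simulation campaign and synthetic ensembles.

The study design varies only the two toxicological response intensities over
the level set {0, 0.1, 1.0, 10.0} and, in one variant, the three feeding-
decline parameters. Four named conditions organise the runs by the ratio
delta = r11/r21:

  a: no microplastic influence (r11 = r21 = 0, burdens frozen at zero)
  b: equal response strength        (delta = 1)
  c: predator much more responsive  (delta = 0.1)
  d: prey much more responsive      (delta = 10)

``paper_campaign`` returns the full registry of these runs plus the
feeding-decline variants (d1 = 0.6, d2 = 0.012, d3 = 0.012 at the three
equal-strength levels). ``random_ensemble`` generates seeded synthetic
scenarios around the baseline for robustness and reproducibility checks:
response intensities log-uniform over three decades, all other rates jittered
by +/-20%, which brackets the study's levels without breaking the model's
sign structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .integrate import SolverSettings, Trajectory, simulate
from .model import ModelParameters, State, ValidationError
from .summaries import SummaryStats, summarize

__all__ = [
    "Scenario",
    "SweepRecord",
    "SweepResult",
    "baseline_parameters",
    "make_condition",
    "feeding_decline_variant",
    "paper_campaign",
    "random_ensemble",
    "run_scenario",
    "run_campaign",
]

LEVELS = (0.1, 1.0, 10.0)
CONDITION_DELTA = {"b": 1.0, "c": 0.1, "d": 10.0}


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified run: parameters, initial state, horizon."""

    name: str
    params: ModelParameters
    init: State
    t_end: float = 10.0
    freeze_toxins: bool = False   # condition a: hold C1 = C2 = 0 throughout
    provenance: str = ""          # condition label or ensemble seed tag

    @property
    def delta(self) -> float | None:
        """Ratio r11/r21 of the response intensities; None when r21 = 0."""
        if self.params.r21 == 0:
            return None
        return self.params.r11 / self.params.r21

    def run_params(self) -> ModelParameters:
        """Parameters actually integrated; freezing zeroes all burden rates."""
        if self.freeze_toxins:
            return replace(self.params, S1=0.0, S2=0.0, g1=0.0, g2=0.0, k=0.0)
        return self.params


@dataclass(frozen=True)
class SweepRecord:
    scenario: Scenario
    stats: SummaryStats


@dataclass(frozen=True)
class SweepResult:
    """One summary per scenario, with enough metadata to regenerate each."""

    records: tuple[SweepRecord, ...]
    settings: SolverSettings

    def __getitem__(self, name: str) -> SweepRecord:
        for r in self.records:
            if r.scenario.name == name:
                return r
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            s, st = r.scenario, r.stats
            rows.append(
                {
                    "scenario": s.name,
                    "r11": s.params.r11,
                    "r21": s.params.r21,
                    "delta": s.delta,
                    "d1": s.params.d1,
                    "d2": s.params.d2,
                    "d3": s.params.d3,
                    "period": st.period,
                    "prey_extinction": st.prey_extinction,
                    "predator_extinction": st.predator_extinction,
                    "outcome": st.outcome,
                    "prey_max": st.prey_range[1],
                    "predator_max": st.predator_range[1],
                }
            )
        return pd.DataFrame(rows)


def baseline_parameters() -> tuple[ModelParameters, State]:
    """The study's parameter table and initial conditions.

    Densities start at (x1, x2) = (100, 10) No./m^3 with zero internal burden;
    the environmental concentration is the surface-water value of 30
    particles/m^3. Response intensities default to zero (set per scenario).
    """
    params = ModelParameters(
        r10=4.1, r20=4.0, r11=0.0, r21=0.0,
        a1=0.052, a2=0.052, d1=0.1, d2=0.002, d3=0.002,
        S1=0.042, S2=0.039, g1=1.2, g2=1.3, k=2.0, CE=30.0,
    )
    return params, State(t=0.0, x1=100.0, x2=10.0, C1=0.0, C2=0.0)


def make_condition(
    label: str, level_pair: tuple[float, float] = (0.0, 0.0), t_end: float = 10.0
) -> Scenario:
    """Build one of the four named conditions at a given (r11, r21) pair.

    Condition a forces r11 = r21 = 0 with burdens frozen at zero; b, c and d
    require the pair's ratio to equal the condition's delta (1, 0.1, 10), with
    levels drawn from {0.1, 1.0, 10.0}.
    """
    params, init = baseline_parameters()
    if label == "a":
        if level_pair != (0.0, 0.0):
            raise ValueError("condition a requires r11 = r21 = 0")
        return Scenario(
            name="condition_a",
            params=params,
            init=init,
            t_end=t_end,
            freeze_toxins=True,
            provenance="condition a",
        )
    if label not in CONDITION_DELTA:
        raise ValueError(f"unknown condition label {label!r}")
    r11, r21 = level_pair
    if r11 not in LEVELS or r21 not in LEVELS:
        raise ValueError(f"levels must come from {LEVELS}")
    delta = CONDITION_DELTA[label]
    if abs(r11 / r21 - delta) > 1e-12:
        raise ValueError(
            f"level pair {level_pair} has ratio {r11 / r21:g}, "
            f"inconsistent with condition {label} (delta = {delta:g})"
        )
    return Scenario(
        name=f"condition_{label}_r11={r11:g}_r21={r21:g}",
        params=replace(params, r11=r11, r21=r21),
        init=init,
        t_end=t_end,
        provenance=f"condition {label}",
    )


def feeding_decline_variant(params: ModelParameters) -> ModelParameters:
    """Raise the feeding-decline parameters to d1=0.6, d2=0.012, d3=0.012.

    The increased-decline variant used to probe whether reduced feeding
    ability changes the dynamics. Idempotent; the result still satisfies the
    sign-structure constraints (a1 - d3 = 0.04 > 0).
    """
    return replace(params, d1=0.6, d2=0.012, d3=0.012)


def paper_campaign(t_end: float = 10.0) -> list[Scenario]:
    """The full registry of the study's named runs.

    Condition a; condition b at (0.1, 0.1), (1, 1), (10, 10); condition c at
    (0.1, 1) and (1, 10); condition d at (1, 0.1) and (10, 1); and the three
    feeding-decline variants at the equal-strength levels.
    """
    scenarios = [make_condition("a", t_end=t_end)]
    for lv in LEVELS:
        scenarios.append(make_condition("b", (lv, lv), t_end=t_end))
    scenarios.append(make_condition("c", (0.1, 1.0), t_end=t_end))
    scenarios.append(make_condition("c", (1.0, 10.0), t_end=t_end))
    scenarios.append(make_condition("d", (1.0, 0.1), t_end=t_end))
    scenarios.append(make_condition("d", (10.0, 1.0), t_end=t_end))
    for lv in LEVELS:
        base = make_condition("b", (lv, lv), t_end=t_end)
        scenarios.append(
            replace(
                base,
                name=f"feeding_decline_r11={lv:g}_r21={lv:g}",
                params=feeding_decline_variant(base.params),
                provenance="feeding-decline variant",
            )
        )
    return scenarios


_JITTERED = ("r10", "r20", "a1", "a2", "d1", "d2", "d3", "S1", "S2", "g1", "g2", "k", "CE")


def random_ensemble(
    n: int,
    seed: int,
    intensity_range: tuple[float, float] = (0.01, 20.0),
    jitter: float = 0.2,
    t_end: float = 10.0,
) -> list[Scenario]:
    """Seeded synthetic scenarios around the baseline.

    Response intensities r11, r21 are drawn log-uniformly over
    ``intensity_range`` (three decades by default, bracketing the study's
    levels); every other rate gets an independent uniform +/-``jitter``
    relative perturbation. Same seed, same list. Each member is validated.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = intensity_range
    if not (0 < lo < hi):
        raise ValueError("intensity_range must satisfy 0 < low < high")
    if not (0 <= jitter < 1):
        raise ValueError("jitter must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    base, init = baseline_parameters()
    out: list[Scenario] = []
    for i in range(n):
        fields = {
            name: float(getattr(base, name) * (1.0 + jitter * rng.uniform(-1.0, 1.0)))
            for name in _JITTERED
        }
        fields["r11"], fields["r21"] = (
            float(v) for v in np.exp(rng.uniform(np.log(lo), np.log(hi), size=2))
        )
        params = ModelParameters(**fields)
        violations = params.violations()
        if violations:  # cannot occur at jitter < 1 with the baseline table
            raise ValidationError("; ".join(violations))
        out.append(
            Scenario(
                name=f"ensemble_seed{seed}_{i:04d}",
                params=params,
                init=init,
                t_end=t_end,
                provenance=f"ensemble seed={seed} member={i}",
            )
        )
    return out


def run_scenario(
    scenario: Scenario, settings: SolverSettings | None = None
) -> tuple[Trajectory, SummaryStats]:
    """Integrate one scenario and summarise it."""
    traj = simulate(scenario.run_params(), scenario.init, scenario.t_end, settings)
    return traj, summarize(traj)


def run_campaign(
    scenarios: list[Scenario], settings: SolverSettings | None = None
) -> SweepResult:
    """Integrate and summarise every scenario; deterministic given settings."""
    if not scenarios:
        raise ValueError("scenario list must be nonempty")
    settings = settings or SolverSettings()
    records = []
    for sc in scenarios:
        try:
            _, stats = run_scenario(sc, settings)
        except Exception as exc:
            raise RuntimeError(f"scenario {sc.name!r} failed: {exc}") from exc
        records.append(SweepRecord(sc, stats))
    return SweepResult(records=tuple(records), settings=settings)
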