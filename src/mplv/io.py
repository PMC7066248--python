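"""Configuration files, trajectory/summary serialization, and plotting.

All artifacts are small and text-based: trajectories as comma-delimited tables
with header ``t,x1,x2,C1,C2``, run summaries as nested YAML documents carrying
parameters, peak tables, period, extinction times, outcome, solver settings
and software version — enough metadata to regenerate every artifact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import __version__
from .integrate import SolverSettings, Trajectory
from .model import ModelParameters, State
from .scenarios import (
    Scenario,
    SweepRecord,
    SweepResult,
    paper_campaign,
    random_ensemble,
)
from .summaries import Extremum, SummaryStats

__all__ = [
    "RunConfig",
    "ConfigError",
    "read_config",
    "resolve_scenarios",
    "write_trajectory",
    "read_trajectory",
    "write_summary",
    "read_summary",
    "plot_run",
]

TRAJECTORY_COLUMNS = ("t", "x1", "x2", "C1", "C2")


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run request: which scenarios, solver settings, outputs."""

    scenario: str                       # scenario name, "campaign" or "ensemble"
    solver: SolverSettings
    outdir: Path
    outputs: tuple[str, ...] = ("summary",)
    ensemble_n: int | None = None
    ensemble_seed: int | None = None
    t_end: float | None = None
    param_overrides: dict[str, float] = dataclasses.field(default_factory=dict)


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_SOLVER_FIELDS = {f.name for f in dataclasses.fields(SolverSettings)}
_TOP_KEYS = {"scenario", "solver", "outdir", "outputs", "ensemble", "t_end"} | _PARAM_FIELDS
_OUTPUTS = {"trajectory", "summary", "plots"}


def read_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ConfigError(f"cannot parse {path}{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    if "scenario" not in raw:
        raise ConfigError("config must name a 'scenario'")

    solver_raw = raw.get("solver") or {}
    bad = set(solver_raw) - _SOLVER_FIELDS
    if bad:
        raise ConfigError(f"unknown solver keys: {', '.join(sorted(bad))}")
    solver = replace(SolverSettings(), **{k: float(v) for k, v in solver_raw.items()})

    outputs = tuple(raw.get("outputs", ["summary"]))
    bad = set(outputs) - _OUTPUTS
    if bad:
        raise ConfigError(f"unknown outputs: {', '.join(sorted(bad))}")

    ens = raw.get("ensemble") or {}
    scenario = str(raw["scenario"])
    if scenario == "ensemble":
        if "n" not in ens or "seed" not in ens:
            raise ConfigError("ensemble scenario requires ensemble: {n, seed}")
    overrides = {k: float(raw[k]) for k in _PARAM_FIELDS if k in raw}
    return RunConfig(
        scenario=scenario,
        solver=solver,
        outdir=Path(raw.get("outdir", "results")),
        outputs=outputs,
        ensemble_n=int(ens["n"]) if "n" in ens else None,
        ensemble_seed=int(ens["seed"]) if "seed" in ens else None,
        t_end=float(raw["t_end"]) if "t_end" in raw else None,
        param_overrides=overrides,
    )


def resolve_scenarios(config: RunConfig) -> list[Scenario]:
    """Expand a config's scenario selector into concrete scenarios."""
    if config.scenario == "ensemble":
        scenarios = random_ensemble(config.ensemble_n, config.ensemble_seed)
    elif config.scenario == "campaign":
        scenarios = paper_campaign()
    else:
        registry = {s.name: s for s in paper_campaign()}
        if config.scenario not in registry:
            raise ConfigError(
                f"unknown scenario {config.scenario!r}; "
                f"known: campaign, ensemble, {', '.join(sorted(registry))}"
            )
        scenarios = [registry[config.scenario]]
    if config.t_end is not None:
        scenarios = [replace(s, t_end=config.t_end) for s in scenarios]
    if config.param_overrides:
        scenarios = [
            replace(s, params=replace(s.params, **config.param_overrides))
            for s in scenarios
        ]
    for s in scenarios:
        s.params.validate()
    return scenarios


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a CSV table at full float precision."""
    if len(traj) == 0:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([traj.t, traj.y]), columns=list(TRAJECTORY_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory(path: str | Path, settings: SolverSettings | None = None) -> Trajectory:
    """Read a trajectory table written by :func:`write_trajectory`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if tuple(df.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(f"{path}: expected columns {TRAJECTORY_COLUMNS}")
    return Trajectory(
        t=df["t"].to_numpy(),
        y=df[["x1", "x2", "C1", "C2"]].to_numpy(),
        settings=settings or SolverSettings(),
    )


def _extremum_to_dict(e: Extremum) -> dict:
    return {"time": float(e.time), "value": float(e.value), "series": e.series, "kind": e.kind}


def _params_to_dict(p: ModelParameters) -> dict:
    return {f.name: float(getattr(p, f.name)) for f in dataclasses.fields(ModelParameters)}


def _settings_to_dict(s: SolverSettings) -> dict:
    return {f.name: float(getattr(s, f.name)) for f in dataclasses.fields(SolverSettings)}


def write_summary(result: SweepResult, path: str | Path) -> Path:
    """Write a sweep summary as a nested YAML document; round-trips losslessly."""
    if not result.records:
        raise ValueError("cannot write an empty sweep result")
    doc = {
        "version": __version__,
        "solver": _settings_to_dict(result.settings),
        "scenarios": [],
    }
    for rec in result.records:
        s, st = rec.scenario, rec.stats
        doc["scenarios"].append(
            {
                "name": s.name,
                "provenance": s.provenance,
                "t_end": float(s.t_end),
                "freeze_toxins": bool(s.freeze_toxins),
                "delta": None if s.delta is None else float(s.delta),
                "parameters": _params_to_dict(s.params),
                "initial_state": {
                    "t": float(s.init.t),
                    "x1": float(s.init.x1),
                    "x2": float(s.init.x2),
                    "C1": float(s.init.C1),
                    "C2": float(s.init.C2),
                },
                "prey_peaks": [
                    _extremum_to_dict(e) for e in st.prey_extrema if e.kind == "max"
                ],
                "prey_troughs": [
                    _extremum_to_dict(e) for e in st.prey_extrema if e.kind == "min"
                ],
                "predator_peaks": [
                    _extremum_to_dict(e) for e in st.predator_extrema if e.kind == "max"
                ],
                "predator_troughs": [
                    _extremum_to_dict(e) for e in st.predator_extrema if e.kind == "min"
                ],
                "period": None if st.period is None else float(st.period),
                "prey_extinction": None
                if st.prey_extinction is None
                else float(st.prey_extinction),
                "predator_extinction": None
                if st.predator_extinction is None
                else float(st.predator_extinction),
                "outcome": st.outcome,
                "prey_range": [float(v) for v in st.prey_range],
                "predator_range": [float(v) for v in st.predator_range],
            }
        )
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_summary(path: str | Path) -> SweepResult:
    """Reload a summary document into an equal :class:`SweepResult`."""
    doc = yaml.safe_load(Path(path).read_text())
    settings = SolverSettings(**doc["solver"])
    records = []
    for sd in doc["scenarios"]:
        params = ModelParameters(**sd["parameters"])
        init = State(**sd["initial_state"])
        scenario = Scenario(
            name=sd["name"],
            params=params,
            init=init,
            t_end=sd["t_end"],
            freeze_toxins=sd["freeze_toxins"],
            provenance=sd["provenance"],
        )
        extrema = {"x1": [], "x2": []}
        for key, series, kind in (
            ("prey_peaks", "x1", "max"),
            ("prey_troughs", "x1", "min"),
            ("predator_peaks", "x2", "max"),
            ("predator_troughs", "x2", "min"),
        ):
            for e in sd[key]:
                extrema[series].append(Extremum(e["time"], e["value"], series, kind))
        for v in extrema.values():
            v.sort(key=lambda e: e.time)
        stats = SummaryStats(
            prey_extrema=tuple(extrema["x1"]),
            predator_extrema=tuple(extrema["x2"]),
            period=sd["period"],
            prey_extinction=sd["prey_extinction"],
            predator_extinction=sd["predator_extinction"],
            outcome=sd["outcome"],
            prey_range=tuple(sd["prey_range"]),
            predator_range=tuple(sd["predator_range"]),
        )
        records.append(SweepRecord(scenario, stats))
    return SweepResult(records=tuple(records), settings=settings)


def plot_run(traj: Trajectory, kind: str, path: str | Path, title: str = "") -> Path:
    """Render a time-series panel or a phase portrait to an image file.

    Time series: time in months on X, densities on Y, prey in blue and
    predator in red. Phase portrait: prey on X, predator on Y.
    """
    if len(traj) == 0:
        raise ValueError("cannot plot an empty trajectory")
    fig, ax = plt.subplots(figsize=(6, 4))
    if kind == "time_series":
        ax.plot(traj.t, traj.x1, color="tab:blue", label="prey $x_1$")
        ax.plot(traj.t, traj.x2, color="tab:red", label="predator $x_2$")
        ax.set_xlim(traj.t[0], traj.t[-1])
        ax.set_xlabel("time (months)")
        ax.set_ylabel("density (No./m$^3$)")
        ax.legend()
    elif kind == "phase_portrait":
        ax.plot(traj.x1, traj.x2, color="tab:green", lw=0.8)
        ax.set_xlabel("prey $x_1$ (No./m$^3$)")
        ax.set_ylabel("predator $x_2$ (No./m$^3$)")
    else:
        raise ValueError(f"unknown plot kind {kind!r}")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
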