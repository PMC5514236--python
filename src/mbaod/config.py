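"""Configuration of an adaptive-trial run, with YAML round-tripping.

An :class:`MBAODConfig` fully determines one batch of adaptive-trial
replicates: the scenario parameters, schedule, criterion, cohort structure,
stopping settings and the master seed. :func:`load_config` reads a YAML file
where every omitted key falls back to the dose-finding scenario defaults
(so an empty file yields the full default study), and unknown keys are
rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import yaml

from . import scenario
from .model import StudyDesign
from .parameters import PopulationParameters


@dataclass(frozen=True)
class MBAODConfig:
    """Settings of one adaptive dose-optimization trial simulation."""

    theta_true: PopulationParameters
    theta_init: PopulationParameters
    initial_design: StudyDesign
    schedule: str = "sparse"
    criterion: str = "lnD"
    cohort_group_n: int = 2
    max_cohorts: int = 50
    dose_grid: tuple[int, ...] = scenario.DEFAULT_DOSE_GRID
    prior_cv: float = 0.10
    n_lhs: int = 10
    n_stop_sim: int = 100_000
    band: tuple[float, float] = (0.60, 1.40)
    ci_level: float = 0.95
    seed: int = 1
    estimation_method: str = "FOCEI"
    update_priors: bool = True

    def __post_init__(self) -> None:
        if self.schedule not in scenario.SCHEDULES:
            raise ValueError(f"config key 'schedule' must be one of {sorted(scenario.SCHEDULES)}")
        if self.criterion not in ("lnD", "ELD"):
            raise ValueError("config key 'criterion' must be 'lnD' or 'ELD'")
        if self.max_cohorts < 1:
            raise ValueError("config key 'max_cohorts' must be >= 1")
        lo, hi = self.band
        if not (lo < 1.0 < hi):
            raise ValueError("config key 'band' must bracket 1 (lower < 1 < upper)")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("config key 'ci_level' must be in (0, 1)")
        if self.cohort_group_n < 1:
            raise ValueError("config key 'cohort_group_n' must be >= 1")
        if self.n_lhs < 1:
            raise ValueError("config key 'n_lhs' must be >= 1")
        if self.n_stop_sim < 1:
            raise ValueError("config key 'n_stop_sim' must be >= 1")
        if self.prior_cv < 0:
            raise ValueError("config key 'prior_cv' must be >= 0")
        object.__setattr__(self, "dose_grid", tuple(int(d) for d in self.dose_grid))
        object.__setattr__(self, "band", (float(lo), float(hi)))

    @property
    def times(self) -> tuple[float, ...]:
        return scenario.SCHEDULES[self.schedule]

    def to_dict(self) -> dict:
        return {
            "theta_true": self.theta_true.as_dict(),
            "theta_init": self.theta_init.as_dict(),
            "initial_design": self.initial_design.as_dict(),
            "schedule": self.schedule,
            "criterion": self.criterion,
            "cohort_group_n": self.cohort_group_n,
            "max_cohorts": self.max_cohorts,
            "dose_grid": {"range": [int(self.dose_grid[0]), int(self.dose_grid[-1])]}
            if self.dose_grid == tuple(range(self.dose_grid[0], self.dose_grid[-1] + 1))
            else list(self.dose_grid),
            "prior_cv": self.prior_cv,
            "n_lhs": self.n_lhs,
            "n_stop_sim": self.n_stop_sim,
            "band": list(self.band),
            "ci_level": self.ci_level,
            "seed": self.seed,
            "estimation_method": self.estimation_method,
            "update_priors": self.update_priors,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(**overrides) -> MBAODConfig:
    """The full dose-finding scenario with optional field overrides."""
    schedule = overrides.pop("schedule", "sparse")
    if schedule not in scenario.SCHEDULES:
        raise ValueError(f"config key 'schedule' must be one of {sorted(scenario.SCHEDULES)}")
    base = MBAODConfig(
        theta_true=scenario.true_parameters(),
        theta_init=scenario.initial_guess(),
        initial_design=scenario.initial_design(schedule),
        schedule=schedule,
    )
    return replace(base, **overrides) if overrides else base


_SIMPLE_KEYS = {
    "schedule",
    "criterion",
    "cohort_group_n",
    "max_cohorts",
    "prior_cv",
    "n_lhs",
    "n_stop_sim",
    "ci_level",
    "seed",
    "estimation_method",
    "update_priors",
}


def config_from_dict(d: dict) -> MBAODConfig:
    d = dict(d or {})
    known = _SIMPLE_KEYS | {"theta_true", "theta_init", "initial_design", "dose_grid", "band"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    overrides: dict = {k: d[k] for k in _SIMPLE_KEYS if k in d}
    if "theta_true" in d:
        overrides["theta_true"] = PopulationParameters.from_dict(d["theta_true"])
    if "theta_init" in d:
        overrides["theta_init"] = PopulationParameters.from_dict(d["theta_init"])
    if "initial_design" in d:
        overrides["initial_design"] = StudyDesign.from_dict(d["initial_design"])
    if "dose_grid" in d:
        g = d["dose_grid"]
        if isinstance(g, dict):
            # {"range": [lo, hi]} shorthand: inclusive integer range.
            lo, hi = g["range"]
            grid = range(int(lo), int(hi) + 1)
        else:
            grid = g
        overrides["dose_grid"] = tuple(int(x) for x in grid)
    if "band" in d:
        overrides["band"] = tuple(float(x) for x in d["band"])
    return default_config(**overrides)


def load_config(path) -> MBAODConfig:
    """Load a YAML config; omitted keys take the scenario defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})
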