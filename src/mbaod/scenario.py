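"""The warfarin-PK-driven sigmoidal EMAX dose-finding scenario.

All constants of the simulated dose-optimization study: true simulation
parameters, the +50% misspecified initial guess of the PD fixed effects,
sparse and rich sampling schedules, the fixed initial two-group design
(0 and 160 mg, four subjects each) and the 0–500 mg integer dose grid.
PK parameters and ω²_CL, ω²_V, σ²_add are fixed (known); the seven
estimated parameters are Base, EMAX, EC50, γ, ω²_EMAX, ω²_EC50 and σ²_prop.
"""

from __future__ import annotations

from .design import DEFAULT_DOSE_GRID
from .model import GroupDesign, StudyDesign
from .parameters import (
    DEFAULT_ESTIMATED,
    FixedEffects,
    PopulationParameters,
    RandomEffectVariances,
)

#: Sparse sampling schedule (h).
T_SPARSE = (0.5, 3.0, 60.0)
#: Rich sampling schedule (h).
T_RICH = (0.5, 2.0, 3.0, 6.0, 24.0, 36.0, 72.0, 120.0)

SCHEDULES = {"sparse": T_SPARSE, "rich": T_RICH}

#: Doses (mg) and group size of the fixed, unoptimized first cohort.
INITIAL_DOSES = (0, 160)
INITIAL_GROUP_N = 4
#: Subjects added per adaptive cohort (one new group).
COHORT_GROUP_N = 2

TRUE_FIXED = FixedEffects(base=1.0, emax=100.0, ec50=7.0, gamma=2.0, cl=0.15, v=8.0, ka=1.0)
#: +50% misspecification on the PD fixed effects; PK assumed known.
GUESS_FIXED = FixedEffects(base=1.5, emax=150.0, ec50=10.5, gamma=3.0, cl=0.15, v=8.0, ka=1.0)

RANDOM_EFFECTS = RandomEffectVariances(
    omega2_emax=0.0625,
    omega2_ec50=0.0625,
    omega2_cl=0.07,
    omega2_v=0.02,
    sigma2_add=0.001,
    sigma2_prop=0.015,
)


def true_parameters() -> PopulationParameters:
    """Θ used to simulate 'reality'."""
    return PopulationParameters(TRUE_FIXED, RANDOM_EFFECTS, DEFAULT_ESTIMATED)


def initial_guess() -> PopulationParameters:
    """Θ̂₀: +50% misspecified PD fixed effects, true random effects."""
    return PopulationParameters(GUESS_FIXED, RANDOM_EFFECTS, DEFAULT_ESTIMATED)


def initial_design(schedule: str = "sparse") -> StudyDesign:
    """The unoptimized first cohort: 0 and 160 mg, four subjects each."""
    times = SCHEDULES[schedule]
    return StudyDesign(
        tuple(GroupDesign(d, INITIAL_GROUP_N, times) for d in INITIAL_DOSES)
    )


def dose_grid() -> tuple[int, ...]:
    return DEFAULT_DOSE_GRID
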