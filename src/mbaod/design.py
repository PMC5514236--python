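"""lnD and ELD (API) design criteria and discrete dose optimization.

lnD-optimality maximizes ln|FIM| of the block-diagonal population FIM at a
point parameter guess. ELD-optimality maximizes the expectation of ln|FIM|
over a normal prior on the estimated fixed effects, approximated by a Latin
hypercube sample from the prior. The only optimized design variable is the
next cohort's dose, a discrete covariate on an integer grid, so optimization
is an exhaustive scan — the returned dose is certifiably the global argmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .fim import elementary_fim_grid, population_fim
from .model import GroupDesign, StudyDesign
from .parameters import BETA_NAMES, PopulationParameters

logger = logging.getLogger(__name__)

#: Default discrete dose grid, 0..500 mg in 1 mg steps.
DEFAULT_DOSE_GRID = tuple(range(0, 501))


def make_dose_grid(doses: Sequence[int]) -> tuple[int, ...]:
    """Validate and canonicalize a dose grid (sorted, unique, non-empty)."""
    grid = sorted({int(d) for d in doses})
    if not grid:
        raise ValueError("dose grid must be non-empty")
    return tuple(grid)


@dataclass(frozen=True)
class ParameterPrior:
    """Independent normal prior on the estimated fixed effects.

    ``mean`` and ``sd`` are keyed by fixed-effect name; ``sd[j] = 0``
    collapses that marginal to a point mass (and the ELD criterion to lnD
    when all entries are zero).
    """

    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        mean = dict(self.mean)
        sd = dict(self.sd)
        if set(mean) != set(sd):
            raise ValueError("prior mean and sd must share the same parameter names")
        unknown = set(mean) - set(BETA_NAMES)
        if unknown:
            raise ValueError(f"prior names must be fixed effects, got {sorted(unknown)}")
        if any(s < 0 for s in sd.values()):
            raise ValueError("prior standard deviations must be >= 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n in BETA_NAMES if n in self.mean)


def lnd_objective(theta: PopulationParameters, design: StudyDesign, *, response=None) -> float:
    """ln|FIM^block-diag(Θ, ξ)|; −inf when the FIM is singular/indefinite."""
    return population_fim(theta, design, form="block_diag", response=response).logdet()


def lhs_sample(prior: ParameterPrior, n: int, seed) -> list[dict[str, float]]:
    """Latin hypercube sample of ``n`` fixed-effect vectors from the prior.

    Per dimension, exactly one draw falls in each of the n equal-probability
    strata of the marginal normal; strata are paired across dimensions by
    independent random permutations. Draws that come out non-positive are
    redrawn within their stratum (the structural model requires positive
    fixed effects); an event counter is logged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = prior.names
    out = np.empty((n, len(names)))
    n_redraws = 0
    for j, name in enumerate(names):
        mean, sd = prior.mean[name], prior.sd[name]
        strata = rng.permutation(n)
        u = (strata + rng.uniform(size=n)) / n
        x = mean + sd * ndtri(u) if sd > 0 else np.full(n, float(mean))
        if sd > 0:
            for _ in range(200):
                bad = x <= 0
                if not bad.any():
                    break
                n_redraws += int(bad.sum())
                u_new = (strata[bad] + rng.uniform(size=int(bad.sum()))) / n
                x[bad] = mean + sd * ndtri(u_new)
            else:
                # Stratum essentially entirely non-positive (degenerately
                # wide prior): pin to a small positive fraction of the mean.
                x[x <= 0] = 1e-3 * abs(mean)
        out[:, j] = x
    if n_redraws:
        logger.info("lhs_sample: redrew %d non-positive draws within their strata", n_redraws)
    return [dict(zip(names, row)) for row in out]


def eld_objective(
    prior: ParameterPrior,
    theta_rest: PopulationParameters,
    design: StudyDesign,
    samples: Sequence[Mapping[str, float]],
    *,
    response=None,
) -> float:
    """Monte-Carlo ELD objective: mean of lnD over prior samples.

    ``theta_rest`` supplies the random-effect variances and any fixed
    (non-sampled) parameters. A sample with a singular FIM contributes −inf,
    making the candidate design non-preferred.
    """
    if len(samples) == 0:
        raise ValueError("need at least one prior sample")
    vals = [
        lnd_objective(theta_rest.with_values(s), design, response=response) for s in samples
    ]
    return float(np.mean(vals))


@dataclass
class OptimizationResult:
    """Outcome of an exhaustive next-dose scan."""

    dose: int
    value: float
    trace: pd.DataFrame = field(repr=False)

    def certify(self) -> bool:
        """True iff the chosen value is >= every candidate's value (always, by construction)."""
        return bool((self.value >= self.trace["objective"].to_numpy() - 0.0).all())


def optimize_next_dose(
    criterion: str,
    theta_or_prior,
    base_design: StudyDesign,
    new_group_n: int,
    grid: Sequence[int],
    seed=None,
    *,
    times: Sequence[float],
    theta_rest: PopulationParameters | None = None,
    n_lhs: int = 10,
    samples: Sequence[Mapping[str, float]] | None = None,
    response=None,
) -> OptimizationResult:
    """Exhaustively choose the next cohort's dose on a discrete grid.

    For every candidate dose, the criterion is evaluated on
    ``base_design`` ∪ {one new group of ``new_group_n`` subjects at that dose,
    sampled at ``times``}. Ties break toward the lowest dose. For ELD the
    same LHS draws (common random numbers) are reused for every candidate;
    pass ``samples`` to supply them, else they are drawn from
    ``theta_or_prior`` (a :class:`ParameterPrior`) with ``seed``.
    """
    grid_arr = np.array(sorted({int(d) for d in grid}))
    if criterion == "lnD":
        thetas = [theta_or_prior]
    elif criterion == "ELD":
        prior: ParameterPrior = theta_or_prior
        if theta_rest is None:
            raise ValueError("ELD optimization requires theta_rest")
        if samples is None:
            samples = lhs_sample(prior, n_lhs, seed)
        thetas = [theta_rest.with_values(s) for s in samples]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    # Per-sample singular FIMs enter as a large finite penalty rather than a
    # literal -inf: a parameter draw that is singular at *every* dose (a
    # degenerate prior sample) must not drown the ranking information of the
    # remaining samples.
    _SINGULAR = -1e10
    objective = np.zeros(len(grid_arr))
    for theta in thetas:
        base = population_fim(theta, base_design, form="block_diag", response=response).values
        elem = elementary_fim_grid(theta, grid_arr, times, form="block_diag", response=response)
        total = base[None, :, :] + new_group_n * elem
        sign, ld = np.linalg.slogdet(total)
        vals = np.where((sign > 0) & np.isfinite(ld), np.maximum(ld, _SINGULAR), _SINGULAR)
        objective = objective + vals / len(thetas)

    best = int(np.argmax(objective))  # first max = lowest dose on the sorted grid
    trace = pd.DataFrame({"dose": grid_arr, "objective": objective})
    return OptimizationResult(dose=int(grid_arr[best]), value=float(objective[best]), trace=trace)
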