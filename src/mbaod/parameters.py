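"""Population-parameter containers for the nonlinear mixed-effects PKPD model.

The population parameter vector Θ = [β, λ] collects the fixed effects β
(typical parameter values), the between-subject variances ω² and the
residual-error variances σ². Random effects are diagonal: each η enters its
parameter multiplicatively as θ_i = β·exp(η), with η ~ N(0, ω²) and no
covariances. A subset of Θ is flagged as *estimated*; the remainder is held
fixed (known) in both design optimization and estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

#: Fixed-effect names, in canonical order.
BETA_NAMES = ("base", "emax", "ec50", "gamma", "cl", "v", "ka")

#: Parameters carrying a between-subject random effect; defines the η order.
ETA_NAMES = ("emax", "ec50", "cl", "v")

OMEGA_NAMES = tuple(f"omega2_{n}" for n in ETA_NAMES)
SIGMA_NAMES = ("sigma2_add", "sigma2_prop")
LAMBDA_NAMES = OMEGA_NAMES + SIGMA_NAMES

#: All parameter names, canonical order: β first, then λ (ω² then σ²).
ALL_NAMES = BETA_NAMES + LAMBDA_NAMES

#: Parameters estimated in the default dose-finding scenario (7 parameters:
#: the four PD fixed effects plus ω²_EMAX, ω²_EC50 and σ²_prop; PK and the
#: remaining variances are fixed to known values).
DEFAULT_ESTIMATED = (
    "base",
    "emax",
    "ec50",
    "gamma",
    "omega2_emax",
    "omega2_ec50",
    "sigma2_prop",
)


class DegenerateModelError(ValueError):
    """Raised when parameter values make the structural model degenerate."""


@dataclass(frozen=True)
class FixedEffects:
    """Typical-value (fixed effect) parameters β of the PKPD model.

    Units: ``base`` and ``emax`` in effect units, ``ec50`` mg/L, ``gamma``
    dimensionless, ``cl`` L/h, ``v`` L, ``ka`` 1/h.
    """

    base: float
    emax: float
    ec50: float
    gamma: float
    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("ec50", "gamma", "cl", "v", "ka"):
            if not getattr(self, name) > 0:
                raise ValueError(f"fixed effect {name!r} must be > 0, got {getattr(self, name)}")
        denom = self.v * self.ka - self.cl
        if abs(denom) <= 1e-10 * max(abs(self.v * self.ka), abs(self.cl)):
            raise DegenerateModelError(
                f"v*ka - cl = {denom} is (near) zero: absorption and elimination "
                "rate constants coincide and the oral one-compartment solution degenerates"
            )

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in BETA_NAMES}


@dataclass(frozen=True)
class RandomEffectVariances:
    """Diagonal random-effect variances λ = [ω²..., σ²_add, σ²_prop]."""

    omega2_emax: float
    omega2_ec50: float
    omega2_cl: float
    omega2_v: float
    sigma2_add: float
    sigma2_prop: float

    def __post_init__(self) -> None:
        for name in LAMBDA_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"variance {name!r} must be >= 0, got {getattr(self, name)}")

    @property
    def omega2(self) -> dict[str, float]:
        """Between-subject variances keyed by parameter name, η order."""
        return {n: float(getattr(self, f"omega2_{n}")) for n in ETA_NAMES}

    def omega_matrix(self) -> np.ndarray:
        """Diagonal Ω (4×4) in :data:`ETA_NAMES` order."""
        return np.diag([getattr(self, f"omega2_{n}") for n in ETA_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in LAMBDA_NAMES}


@dataclass(frozen=True)
class PopulationParameters:
    """Full parameter vector Θ = [β, λ] with the estimated-parameter mask."""

    fixed: FixedEffects
    random: RandomEffectVariances
    estimated: tuple[str, ...] = DEFAULT_ESTIMATED

    def __post_init__(self) -> None:
        unknown = [n for n in self.estimated if n not in ALL_NAMES]
        if unknown:
            raise ValueError(f"unknown estimated parameter names: {unknown}")
        # Canonical ordering of the mask, regardless of input order.
        ordered = tuple(n for n in ALL_NAMES if n in set(self.estimated))
        object.__setattr__(self, "estimated", ordered)

    # -- value access -------------------------------------------------------

    def value(self, name: str) -> float:
        if name in BETA_NAMES:
            return float(getattr(self.fixed, name))
        if name in LAMBDA_NAMES:
            return float(getattr(self.random, name))
        raise KeyError(name)

    def with_value(self, name: str, value: float) -> "PopulationParameters":
        """A copy with one parameter replaced (validity re-checked)."""
        if name in BETA_NAMES:
            return replace(self, fixed=replace(self.fixed, **{name: float(value)}))
        if name in LAMBDA_NAMES:
            return replace(self, random=replace(self.random, **{name: float(value)}))
        raise KeyError(name)

    def with_values(self, values: Mapping[str, float]) -> "PopulationParameters":
        theta = self
        for name, val in values.items():
            theta = theta.with_value(name, val)
        return theta

    # -- estimated-parameter bookkeeping ------------------------------------

    @property
    def estimated_beta(self) -> tuple[str, ...]:
        return tuple(n for n in self.estimated if n in BETA_NAMES)

    @property
    def estimated_lambda(self) -> tuple[str, ...]:
        return tuple(n for n in self.estimated if n in LAMBDA_NAMES)

    def estimated_values(self) -> dict[str, float]:
        return {n: self.value(n) for n in self.estimated}

    def omega_matrix(self) -> np.ndarray:
        return self.random.omega_matrix()

    def as_dict(self) -> dict:
        return {
            "fixed": self.fixed.as_dict(),
            "random": self.random.as_dict(),
            "estimated": list(self.estimated),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationParameters":
        return cls(
            fixed=FixedEffects(**d["fixed"]),
            random=RandomEffectVariances(**d["random"]),
            estimated=tuple(d.get("estimated", DEFAULT_ESTIMATED)),
        )


def canonical_order(names: Iterable[str]) -> tuple[str, ...]:
    """Sort parameter names into the canonical β-then-λ order."""
    names = set(names)
    return tuple(n for n in ALL_NAMES if n in names)
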