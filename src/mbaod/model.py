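"""PKPD response model and trial-data simulation.

The response is a sigmoidal EMAX pharmacodynamic model driven by the
concentration of a one-compartment, first-order-absorption oral PK model
(warfarin-like parameter values). Observations carry a combined additive and
proportional residual error:

    y_ij = (Base + C_ij^γ·EMAX_i / (C_ij^γ + EC50_i^γ)) · (1 + ε_prop) + ε_add

Individual parameters are log-normal around the typical values,
θ_i = β·exp(η_i), for EMAX, EC50, CL and V.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ETA_NAMES,
    DegenerateModelError,
    FixedEffects,
    PopulationParameters,
)

#: Maximum dose (mg) of the discrete dose covariate.
MAX_DOSE = 500


# ---------------------------------------------------------------------------
# structural model
# ---------------------------------------------------------------------------

def pk_concentration(t, dose, cl, v, ka, *, tol: float = 1e-10):
    """Concentration (mg/L) of the oral one-compartment model.

    C(t) = dose·ka/(v·ka − cl) · (exp(−(cl/v)·t) − exp(−ka·t)).

    All arguments broadcast. Equivalent to the textbook elimination-rate
    parameterization with ke = cl/v. Raises :class:`DegenerateModelError`
    when |v·ka − cl| falls below ``tol`` relative to its operands (the
    solution has a removable singularity at ka = ke that this model form
    does not handle).
    """
    t = np.asarray(t, dtype=float)
    dose = np.asarray(dose, dtype=float)
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    ka = np.asarray(ka, dtype=float)
    denom = v * ka - cl
    scale = np.maximum(np.abs(v * ka), np.abs(cl))
    if np.any(np.abs(denom) <= tol * np.maximum(scale, 1.0)):
        raise DegenerateModelError("v*ka - cl is (near) zero: degenerate absorption model")
    ke = cl / v
    return dose * ka / denom * (np.exp(-ke * t) - np.exp(-ka * t))


def effect_mean(conc, base, emax, ec50, gamma):
    """Deterministic sigmoidal EMAX effect: base + C^γ·emax/(C^γ + ec50^γ).

    ``0^γ`` is taken as its limit 0 for γ > 0, so zero concentration returns
    the baseline exactly. Broadcasts over all arguments.
    """
    conc = np.asarray(conc, dtype=float)
    base = np.asarray(base, dtype=float)
    emax = np.asarray(emax, dtype=float)
    ec50 = np.asarray(ec50, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    safe = np.where(conc > 0.0, conc, 1.0)
    cg = np.where(conc > 0.0, np.power(safe, gamma), 0.0)
    eg = np.power(ec50, gamma)
    return base + cg * emax / (cg + eg)


def pkpd_response(fixed: FixedEffects, eta, dose, times):
    """Noise-free response at individual random effects ``eta``.

    Parameters
    ----------
    fixed
        Typical values β.
    eta
        Array of shape ``(..., 4)`` in :data:`~mbaod.parameters.ETA_NAMES`
        order (EMAX, EC50, CL, V); zeros give the typical individual.
    dose
        Scalar or array broadcastable against ``eta[..., 0]``.
    times
        1-D array of sampling times (h), appended as the last axis.

    Returns
    -------
    ndarray of shape ``broadcast(eta[..., 0], dose).shape + (T,)``.
    """
    eta = np.asarray(eta, dtype=float)
    times = np.asarray(times, dtype=float)
    e = np.exp(eta)
    emax_i = fixed.emax * e[..., 0]
    ec50_i = fixed.ec50 * e[..., 1]
    cl_i = fixed.cl * e[..., 2]
    v_i = fixed.v * e[..., 3]
    dose = np.broadcast_to(np.asarray(dose, dtype=float), np.broadcast_shapes(np.shape(dose), emax_i.shape))
    conc = pk_concentration(
        times, dose[..., None], cl_i[..., None], v_i[..., None], fixed.ka
    )
    return effect_mean(conc, fixed.base, emax_i[..., None], ec50_i[..., None], fixed.gamma)


@dataclass(frozen=True)
class IndividualParameters:
    """One subject's realized parameters θ_i = g(β, η_i)."""

    base: float
    emax: float
    ec50: float
    gamma: float
    cl: float
    v: float
    ka: float


def individual_parameters(beta: FixedEffects, eta) -> IndividualParameters:
    """Construct θ_i from β and the η vector (EMAX, EC50, CL, V order)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(ETA_NAMES),):
        raise ValueError(f"eta must have shape ({len(ETA_NAMES)},), got {eta.shape}")
    e = np.exp(eta)
    return IndividualParameters(
        base=beta.base,
        emax=beta.emax * e[0],
        ec50=beta.ec50 * e[1],
        gamma=beta.gamma,
        cl=beta.cl * e[2],
        v=beta.v * e[3],
        ka=beta.ka,
    )


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDesign:
    """An elementary design: one dose arm with ``n`` subjects sampled at ``times``."""

    dose: int
    n: int
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if int(self.dose) != self.dose or not (0 <= self.dose <= MAX_DOSE):
            raise ValueError(f"dose must be an integer in [0, {MAX_DOSE}] mg, got {self.dose}")
        object.__setattr__(self, "dose", int(self.dose))
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        times = tuple(float(t) for t in self.times)
        if len(times) == 0 or any(t < 0 for t in times) or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise ValueError("times must be non-empty, non-negative and strictly increasing")
        object.__setattr__(self, "times", times)


@dataclass(frozen=True)
class StudyDesign:
    """A population design ξ: a list of group (elementary) designs."""

    groups: tuple[GroupDesign, ...]

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        if len(groups) == 0:
            raise ValueError("a study design needs at least one group")
        object.__setattr__(self, "groups", groups)

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    def add_group(self, group: GroupDesign) -> "StudyDesign":
        return StudyDesign(self.groups + (group,))

    def as_dict(self) -> list[dict]:
        return [
            {"dose": g.dose, "n": g.n, "times": list(g.times)} for g in self.groups
        ]

    @classmethod
    def from_dict(cls, items: Iterable[dict]) -> "StudyDesign":
        return cls(tuple(GroupDesign(d["dose"], d["n"], tuple(d["times"])) for d in items))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class TrialDataset:
    """Simulated observations, tidy long format.

    ``df`` columns: ``id`` (subject), ``cohort``, ``dose`` (mg), ``time`` (h),
    ``dv`` (observed effect). ``etas`` retains each subject's true random
    effects (one row per subject, columns ``eta_<name>``) for diagnostics;
    it is not part of the CSV serialization contract.
    """

    df: pd.DataFrame
    etas: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("id", "cohort", "dose", "time", "dv")

    @property
    def n_id(self) -> int:
        return int(self.df["id"].nunique())

    def __len__(self) -> int:
        return len(self.df)

    def append(self, other: "TrialDataset") -> "TrialDataset":
        overlap = set(self.df["id"]) & set(other.df["id"])
        if overlap:
            raise ValueError(f"subject ids repeated across datasets: {sorted(overlap)[:5]}")
        return TrialDataset(
            pd.concat([self.df, other.df], ignore_index=True),
            pd.concat([self.etas, other.etas], ignore_index=True),
        )

    def to_csv(self, path_or_buf) -> None:
        # %.17g guarantees exact float64 round-tripping.
        self.df.to_csv(path_or_buf, index=False, columns=list(self.COLUMNS), float_format="%.17g")

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrialDataset":
        df = pd.read_csv(path_or_buf, float_precision="round_trip")
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
        return cls(df[list(cls.COLUMNS)].copy())

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def simulate_dataset(
    design: StudyDesign,
    theta_true: PopulationParameters,
    seed,
    *,
    cohort: int = 1,
    start_id: int = 1,
    response=None,
) -> TrialDataset:
    """Simulate one dataset from the true parameters under ``design``.

    Each subject gets an independent RNG stream spawned from ``seed`` (an int
    or :class:`numpy.random.SeedSequence`), so datasets are reproducible and
    extending a design never perturbs earlier subjects. Per subject:
    η ~ N(0, Ω); per observation: ε_add ~ N(0, σ²_add), ε_prop ~ N(0, σ²_prop);
    dv = f(θ_i)·(1 + ε_prop) + ε_add. Negative observations are retained.
    """
    if response is None:
        response = pkpd_response
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(design.n_total)
    omega_sd = np.sqrt(np.diag(theta_true.omega_matrix()))
    s_add = np.sqrt(theta_true.random.sigma2_add)
    s_prop = np.sqrt(theta_true.random.sigma2_prop)

    rows = []
    eta_rows = []
    sid = start_id
    k = 0
    for group in design.groups:
        times = np.asarray(group.times)
        for _ in range(group.n):
            rng = np.random.default_rng(children[k])
            k += 1
            eta = rng.standard_normal(len(ETA_NAMES)) * omega_sd
            f = response(theta_true.fixed, eta, group.dose, times)
            eps_prop = rng.standard_normal(len(times)) * s_prop
            eps_add = rng.standard_normal(len(times)) * s_add
            dv = f * (1.0 + eps_prop) + eps_add
            for t, y in zip(times, dv):
                rows.append((sid, cohort, group.dose, t, y))
            eta_rows.append((sid, *eta))
            sid += 1
    df = pd.DataFrame(rows, columns=list(TrialDataset.COLUMNS))
    etas = pd.DataFrame(eta_rows, columns=["id"] + [f"eta_{n}" for n in ETA_NAMES])
    return TrialDataset(df, etas)
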