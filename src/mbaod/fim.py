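"""FO linearization and Fisher information matrices for the NLMEM.

The model is linearized around η = 0, ε = 0 (first-order approximation):

    E(y) ≈ f(β, η=0)
    V(y) ≈ L·Ω·Lᵀ + diag(σ²_prop·f² + σ²_add),   L = ∂f/∂η |_{η=0}

The per-subject information over the estimated parameters (β block first,
then λ) is assembled either in *full* form,

    FIM = ½ [[A, C], [Cᵀ, B]],
    A = 2·(∂E/∂β)ᵀ V⁻¹ (∂E/∂β) + tr(∂V/∂β · V⁻¹ · ∂V/∂β' · V⁻¹)
    B = tr(∂V/∂λ · V⁻¹ · ∂V/∂λ' · V⁻¹)
    C = tr(∂V/∂β · V⁻¹ · ∂V/∂λ · V⁻¹)

or in the *block-diagonal* form that drops the C block and reduces A to
2·(∂E/∂β)ᵀ V⁻¹ (∂E/∂β). The block-diagonal form is the default: it is the
one the design criteria maximize. The population FIM for a design ξ with
groups of s_i identical subjects is Σ_i s_i·FIM_i.

Parameter derivatives use central finite differences (relative step 1e-5,
absolute floor 1e-8); fixed (non-estimated) parameters are excluded from
differentiation entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GroupDesign, StudyDesign, pkpd_response
from .parameters import BETA_NAMES, ETA_NAMES, PopulationParameters

#: Relative step for central differences w.r.t. population parameters.
REL_STEP = 1e-5
#: Absolute step floor (parameters can legitimately be tiny).
ABS_STEP = 1e-8
#: Step for the η-Jacobian (η is dimensionless, typical scale ~ω ≈ 0.25).
ETA_STEP = 1e-5


class PositiveDefiniteError(np.linalg.LinAlgError):
    """Raised when a required covariance/variance matrix is not positive definite."""


@dataclass
class MomentApproximation:
    """FO-approximated mean vector and variance matrix over a group's times."""

    mean: np.ndarray
    variance: np.ndarray


@dataclass
class FisherMatrix:
    """A Fisher information matrix with its parameter-name index."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.names)
        if self.values.shape != (p, p):
            raise ValueError(f"matrix shape {self.values.shape} does not match {p} names")

    def logdet(self) -> float:
        """ln|FIM|, or −inf when the matrix is singular/indefinite."""
        sign, ld = np.linalg.slogdet(self.values)
        return float(ld) if sign > 0 and np.isfinite(ld) else -np.inf

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf) -> "FisherMatrix":
        import pandas as pd

        df = pd.read_csv(path_or_buf, index_col=0)
        return cls(df.to_numpy(), tuple(df.columns))


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def _moments_grid(theta: PopulationParameters, doses: np.ndarray, times: np.ndarray, response):
    """FO mean (D, T) and variance (D, T, T) batched over a dose grid."""
    D = len(doses)
    K = len(ETA_NAMES)
    T = len(times)
    eta0 = np.zeros((D, K))
    f0 = response(theta.fixed, eta0, doses, times)  # (D, T)

    L = np.empty((D, T, K))
    for k in range(K):
        step = np.zeros(K)
        step[k] = ETA_STEP
        fp = response(theta.fixed, eta0 + step, doses, times)
        fm = response(theta.fixed, eta0 - step, doses, times)
        L[:, :, k] = (fp - fm) / (2.0 * ETA_STEP)

    omega = theta.omega_matrix()
    ruv = theta.random.sigma2_prop * f0**2 + theta.random.sigma2_add  # (D, T)
    V = np.einsum("dtk,kl,dsl->dts", L, omega, L)
    V[:, np.arange(T), np.arange(T)] += ruv
    return f0, V


def fo_moments(
    theta: PopulationParameters, group: GroupDesign, *, response=None, jitter_tol: float = 1e-10
) -> MomentApproximation:
    """FO-approximated E(y) and V(y) for one group (elementary design).

    Raises :class:`PositiveDefiniteError` if V(y) fails a Cholesky
    factorization after adding a ``jitter_tol``-scaled diagonal jitter.
    """
    response = response or pkpd_response
    doses = np.asarray([group.dose], dtype=float)
    times = np.asarray(group.times, dtype=float)
    f0, V = _moments_grid(theta, doses, times, response)
    mean, var = f0[0], V[0]
    try:
        np.linalg.cholesky(var + jitter_tol * np.trace(var) / len(times) * np.eye(len(times)))
    except np.linalg.LinAlgError as exc:
        raise PositiveDefiniteError(
            f"FO variance for group dose={group.dose} is not positive definite"
        ) from exc
    return MomentApproximation(mean=mean, variance=var)


# ---------------------------------------------------------------------------
# information matrices
# ---------------------------------------------------------------------------

def _step_for(value: float) -> float:
    h = max(REL_STEP * abs(value), ABS_STEP)
    if value > 0:
        # keep central differences on the feasible (positive) side for
        # positivity-constrained parameters arbitrarily close to zero
        h = min(h, 0.5 * value)
    return h


def elementary_fim_grid(
    theta: PopulationParameters,
    doses,
    times,
    form: str = "block_diag",
    *,
    response=None,
) -> np.ndarray:
    """Per-subject FIMs for every dose in ``doses`` at once, shape (D, P, P).

    This is the batched path used by the exhaustive dose scans; each slice
    equals :func:`elementary_fim` of the corresponding one-subject group.
    """
    if form not in ("full", "block_diag"):
        raise ValueError(f"unknown FIM form {form!r}")
    response = response or pkpd_response
    doses = np.asarray(doses, dtype=float)
    times = np.asarray(times, dtype=float)
    D, T = len(doses), len(times)

    beta_est = theta.estimated_beta
    lambda_est = theta.estimated_lambda
    names = beta_est + lambda_est
    nb, nl = len(beta_est), len(lambda_est)
    P = nb + nl

    E0, V0 = _moments_grid(theta, doses, times, response)
    try:
        Vinv = np.linalg.inv(V0)
    except np.linalg.LinAlgError as exc:
        raise PositiveDefiniteError("singular FO variance in FIM assembly") from exc

    # Central-difference derivatives of E and V w.r.t. each estimated parameter.
    dE = np.zeros((P, D, T))
    dV = np.zeros((P, D, T, T))
    for p, name in enumerate(names):
        val = theta.value(name)
        h = _step_for(val)
        Ep, Vp = _moments_grid(theta.with_value(name, val + h), doses, times, response)
        Em, Vm = _moments_grid(theta.with_value(name, val - h), doses, times, response)
        dE[p] = (Ep - Em) / (2.0 * h)
        dV[p] = (Vp - Vm) / (2.0 * h)

    F = np.zeros((D, P, P))
    dEb = np.moveaxis(dE[:nb], 0, -1)  # (D, T, nb)
    # β mean-block: ½·2·(∂E/∂β)ᵀV⁻¹(∂E/∂β)
    F[:, :nb, :nb] = np.einsum("dti,dts,dsj->dij", dEb, Vinv, dEb)

    if form == "block_diag":
        W = np.einsum("dts,pdsu->pdtu", Vinv, dV[nb:])  # (nl, D, T, T)
        F[:, nb:, nb:] = 0.5 * np.einsum("pdtu,qdut->dpq", W, W)
    else:
        W = np.einsum("dts,pdsu->pdtu", Vinv, dV)  # (P, D, T, T)
        tr = 0.5 * np.einsum("pdtu,qdut->dpq", W, W)
        F[:, :nb, :nb] += tr[:, :nb, :nb]
        F[:, :nb, nb:] = tr[:, :nb, nb:]
        F[:, nb:, :nb] = tr[:, nb:, :nb]
        F[:, nb:, nb:] = tr[:, nb:, nb:]

    return 0.5 * (F + np.swapaxes(F, 1, 2))  # enforce exact symmetry


def elementary_fim(
    theta: PopulationParameters,
    group: GroupDesign,
    form: str = "block_diag",
    *,
    response=None,
) -> FisherMatrix:
    """Per-subject Fisher information for one elementary design."""
    fo_moments(theta, group, response=response)  # surfaces PD errors naming the group
    F = elementary_fim_grid(theta, [group.dose], group.times, form, response=response)[0]
    names = theta.estimated_beta + theta.estimated_lambda
    return FisherMatrix(F, names)


def population_fim(
    theta: PopulationParameters,
    design: StudyDesign,
    form: str = "block_diag",
    *,
    response=None,
) -> FisherMatrix:
    """Population FIM: Σ_i s_i · FIM_i over the design's groups."""
    names = theta.estimated_beta + theta.estimated_lambda
    total = np.zeros((len(names), len(names)))
    for group in design.groups:
        F = elementary_fim_grid(theta, [group.dose], group.times, form, response=response)[0]
        total += group.n * F
    return FisherMatrix(total, names)
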