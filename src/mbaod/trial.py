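"""The adaptive-trial loop: optimize → simulate → estimate → stop-check → update.

Each replicate starts from a fixed, unoptimized first cohort (two groups at
0 and 160 mg, four subjects each), simulated at the true parameters and
fitted from the misspecified initial guess. Every later cohort adds one
group of two subjects at a dose chosen by exhaustive lnD or ELD
optimization under the current guess (and, for ELD, the current prior),
re-fits all accumulated data and evaluates the stopping rule.

The stopping rule simulates fixed-effect vectors from a multivariate
Student-t distribution located at β̂ with scale matrix
S = COV_β̂·(df − 2)/df and df = n_ID − (n_β̂ + n_λ̂/2) — so that the draw
covariance equals COV_β̂ — pushes each draw through the typical-individual
response at every (dose arm, sampling time), and stops the trial when every
empirical 95% CI lies within 60–140% of the prediction at β̂.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import MBAODConfig, config_from_dict
from .design import OptimizationResult, ParameterPrior, optimize_next_dose
from .estimation import EstimationResult, fit_nlmem
from .fim import FisherMatrix, population_fim
from .model import GroupDesign, StudyDesign, TrialDataset, simulate_dataset
from .parameters import PopulationParameters

logger = logging.getLogger(__name__)


class TooFewSubjectsError(ValueError):
    """Degrees of freedom of the stopping distribution are non-positive."""


class StoppingDeferred(ValueError):
    """df ≤ 2: the t-scale matrix is undefined, stopping deferred to the next cohort."""


# ---------------------------------------------------------------------------
# stopping-criterion pieces
# ---------------------------------------------------------------------------

def degrees_of_freedom(n_id: int, n_beta: int, n_lambda: int) -> float:
    """df = n_ID − (n_β + n_λ/2); raises when the result is ≤ 0."""
    if n_id < 0 or n_beta < 0 or n_lambda < 0:
        raise ValueError("counts must be non-negative")
    df = n_id - (n_beta + n_lambda / 2.0)
    if df <= 0:
        raise TooFewSubjectsError(
            f"df = {df} <= 0 with n_id={n_id}, n_beta={n_beta}, n_lambda={n_lambda}"
        )
    return float(df)


def scale_matrix(cov_beta: np.ndarray, df: float) -> np.ndarray:
    """Multivariate-t scale S = COV·(df − 2)/df, so Cov(draws) = COV."""
    if df <= 2:
        raise StoppingDeferred(f"df = {df} <= 2: t-distribution covariance undefined")
    cov_beta = np.asarray(cov_beta, dtype=float)
    S = cov_beta * (df - 2.0) / df
    return 0.5 * (S + S.T)


def sample_fixed_effects(beta_hat, S, df: float, n: int, seed) -> np.ndarray:
    """``n`` multivariate-t draws with location β̂, scale S, ``df`` d.o.f."""
    if n < 1:
        raise ValueError("n must be >= 1")
    beta_hat = np.asarray(beta_hat, dtype=float)
    S = np.asarray(S, dtype=float)
    rng = np.random.default_rng(seed)
    # Scale may be PSD (e.g. exactly zero); factor via eigendecomposition.
    w, Q = np.linalg.eigh(0.5 * (S + S.T))
    L = Q * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, len(beta_hat))) @ L.T
    u = rng.chisquare(df, size=n) / df
    return beta_hat + z / np.sqrt(u)[:, None]


@dataclass
class StoppingReport:
    """Band check of the simulated effect-prediction CIs, per (dose, time)."""

    stop: bool
    table: pd.DataFrame  # columns: dose, time, ci_lower, ci_upper, reference, within
    df: float
    n_sim: int
    evaluated: bool = True
    reason: str = ""

    @classmethod
    def deferred(cls, reason: str) -> "StoppingReport":
        return cls(
            stop=False,
            table=pd.DataFrame(
                columns=["dose", "time", "ci_lower", "ci_upper", "reference", "within"]
            ),
            df=float("nan"),
            n_sim=0,
            evaluated=False,
            reason=reason,
        )


def evaluate_stopping(
    sim_beta: np.ndarray,
    beta_names: Sequence[str],
    theta_rest: PopulationParameters,
    design: StudyDesign,
    band: tuple[float, float] = (0.60, 1.40),
    level: float = 0.95,
    *,
    df: float = float("nan"),
) -> StoppingReport:
    """Check the simulated typical-effect CIs against the prediction band.

    For every (dose arm, sampling time) the typical-individual (η = 0)
    response is computed under each simulated fixed-effect vector; the
    empirical ``level`` CI must lie inside ``band`` times the reference
    response (the prediction at β̂, i.e. at ``theta_rest``'s fixed effects).
    The interval check is closed: a CI exactly touching the band edge is
    within. A (near-)zero reference auto-fails that point, since the band is
    then undefined; non-finite simulated responses are dropped from the
    quantiles with a logged warning. Fully vectorized over draws; the
    structural PKPD model is evaluated directly.
    """
    from .model import effect_mean, pk_concentration

    sim_beta = np.atleast_2d(np.asarray(sim_beta, dtype=float))
    if sim_beta.shape[0] == 0:
        raise ValueError("sim_beta must be non-empty")
    beta_names = tuple(beta_names)
    n_sim = sim_beta.shape[0]
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0

    # Per-draw fixed-effect columns: sampled where present, β̂/fixed otherwise.
    col = {}
    for name in ("base", "emax", "ec50", "gamma", "cl", "v", "ka"):
        if name in beta_names:
            col[name] = sim_beta[:, beta_names.index(name)][:, None]  # (n_sim, 1)
        else:
            col[name] = np.full((1, 1), theta_rest.value(name))

    # Unique dose arms, stable order of first appearance; shared schedule.
    doses = list(dict.fromkeys(g.dose for g in design.groups))
    times = np.asarray(design.groups[0].times, dtype=float)

    rows = []
    all_within = True
    fx = theta_rest.fixed
    for dose in doses:
        ref_conc = pk_concentration(times, dose, fx.cl, fx.v, fx.ka)
        ref = effect_mean(ref_conc, fx.base, fx.emax, fx.ec50, fx.gamma)  # (T,)
        with np.errstate(all="ignore"):
            conc = pk_concentration(times, dose, col["cl"], col["v"], col["ka"])
            sims = effect_mean(conc, col["base"], col["emax"], col["ec50"], col["gamma"])
        sims = np.broadcast_to(sims, (n_sim, len(times)))
        n_bad = int(np.sum(~np.isfinite(sims).all(axis=1)))
        if n_bad:
            logger.warning(
                "stopping: %d/%d simulated responses non-finite at dose %s; excluded",
                n_bad, n_sim, dose,
            )
        with np.errstate(all="ignore"):
            ci_lo = np.nanquantile(sims, lo_q, axis=0)
            ci_hi = np.nanquantile(sims, hi_q, axis=0)
        for j, t in enumerate(times):
            r = float(ref[j])
            if abs(r) < 1e-12:
                within = False
                logger.warning("stopping: zero reference response at dose %s, t=%s", dose, t)
            else:
                b_lo, b_hi = sorted((band[0] * r, band[1] * r))
                within = bool(b_lo <= ci_lo[j] and ci_hi[j] <= b_hi)
            all_within &= within
            rows.append((dose, t, float(ci_lo[j]), float(ci_hi[j]), r, within))

    table = pd.DataFrame(
        rows, columns=["dose", "time", "ci_lower", "ci_upper", "reference", "within"]
    )
    return StoppingReport(stop=bool(all_within), table=table, df=df, n_sim=n_sim)


# ---------------------------------------------------------------------------
# guess / prior updating
# ---------------------------------------------------------------------------

def update_guess(
    previous: PopulationParameters, fit: EstimationResult
) -> PopulationParameters:
    """Replace estimated entries by their estimates; FIX entries untouched."""
    if not fit.converged:
        logger.info("update_guess: fit not converged, keeping previous guess")
        return previous
    return previous.with_values(fit.theta_hat.estimated_values())


def update_prior(previous: ParameterPrior, fit: EstimationResult) -> ParameterPrior:
    """Set the ELD prior to (β̂, sqrt diag COV_β̂) from the latest fit.

    A repaired (nearest-PD) or absent covariance keeps the previous standard
    deviations: a failed covariance step usually means the fit sits on an
    unidentified ridge, and its clipped-eigenvalue diagonal (often 1e6+)
    would turn the prior into noise rather than a hedge.
    """
    if fit.cov_beta is None or fit.cov_repaired:
        logger.info("update_prior: covariance absent or repaired, keeping previous sd")
        if fit.converged:
            return ParameterPrior(mean=dict(fit.beta_hat), sd=dict(previous.sd))
        return previous
    sd = {
        n: float(np.sqrt(max(fit.cov_beta[i, i], 0.0)))
        for i, n in enumerate(fit.beta_names)
    }
    return ParameterPrior(mean=dict(fit.beta_hat), sd=sd)


# ---------------------------------------------------------------------------
# trial records
# ---------------------------------------------------------------------------

@dataclass
class CohortRecord:
    """Everything recorded about one adaptive cohort."""

    index: int
    chosen_dose: int | None
    criterion_value: float | None
    fit: EstimationResult
    stopping: StoppingReport
    cumulative_design: StudyDesign
    fim_true_logdet: float
    fim_true: FisherMatrix = field(repr=False)
    optimization_trace: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class TrialHistory:
    """One complete adaptive-trial replicate."""

    config: MBAODConfig
    replicate: int
    cohorts: list[CohortRecord]
    status: str  # "stopped" | "max-cohorts-reached"
    data: TrialDataset | None = None  # cumulative simulated observations

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts)

    @property
    def total_n_id(self) -> int:
        return self.cohorts[-1].cumulative_design.n_total

    @property
    def final_fit(self) -> EstimationResult:
        return self.cohorts[-1].fit

    def chosen_doses(self) -> list[int]:
        return [c.chosen_dose for c in self.cohorts if c.chosen_dose is not None]


def _cohort_seed(config: MBAODConfig, replicate: int, cohort: int, stream: int):
    """Independent, reproducible stream per (replicate, cohort, purpose)."""
    return np.random.SeedSequence(
        entropy=[int(config.seed) & 0x7FFFFFFF, replicate, cohort, stream]
    )


# ---------------------------------------------------------------------------
# the MBAOD loop
# ---------------------------------------------------------------------------

def run_mbaod(config: MBAODConfig, replicate: int = 0) -> TrialHistory:
    """Run one adaptive-trial replicate to its stopping point.

    Seeds derive from ``(config.seed, replicate, cohort, stream)``, so
    replicates are independent and bitwise reproducible, and per-cohort
    streams (design LHS, data simulation, estimation jitter, stopping-rule
    draws) never interact. Estimation or covariance failures are recorded
    per cohort and the loop continues with the last usable estimates.
    """
    theta_true = config.theta_true
    guess = config.theta_init
    prior = ParameterPrior(
        mean={n: guess.value(n) for n in guess.estimated_beta},
        sd={n: config.prior_cv * guess.value(n) for n in guess.estimated_beta},
    )
    n_beta = len(theta_true.estimated_beta)
    n_lambda = len(theta_true.estimated_lambda)

    design: StudyDesign | None = None
    data: TrialDataset | None = None
    cohorts: list[CohortRecord] = []
    status = "max-cohorts-reached"

    for k in range(1, config.max_cohorts + 1):
        chosen_dose = None
        crit_value = None
        trace = None
        if k == 1:
            design = config.initial_design
            new_design = design
        else:
            if config.criterion == "lnD":
                opt = optimize_next_dose(
                    "lnD",
                    guess,
                    design,
                    config.cohort_group_n,
                    config.dose_grid,
                    times=config.times,
                )
            else:
                opt = optimize_next_dose(
                    "ELD",
                    prior,
                    design,
                    config.cohort_group_n,
                    config.dose_grid,
                    seed=_cohort_seed(config, replicate, k, 0),
                    times=config.times,
                    theta_rest=guess,
                    n_lhs=config.n_lhs,
                )
            chosen_dose, crit_value, trace = opt.dose, opt.value, opt.trace
            group = GroupDesign(opt.dose, config.cohort_group_n, config.times)
            new_design = StudyDesign((group,))
            design = design.add_group(group)

        new_data = simulate_dataset(
            new_design,
            theta_true,
            _cohort_seed(config, replicate, k, 1),
            cohort=k,
            start_id=1 if data is None else int(data.df["id"].max()) + 1,
        )
        data = new_data if data is None else data.append(new_data)

        fit = fit_nlmem(
            data,
            guess,
            config.estimation_method,
            seed=_cohort_seed(config, replicate, k, 2),
        )
        guess = update_guess(guess, fit)
        if config.update_priors:
            prior = update_prior(prior, fit)
        else:
            # Frozen-sd mode: the prior width stays fixed but its location
            # tracks the current guess (sd=0 then makes ELD replay lnD).
            prior = ParameterPrior(
                mean={n: guess.value(n) for n in guess.estimated_beta},
                sd=dict(prior.sd),
            )

        fim_true = population_fim(theta_true, design, form="block_diag")

        # Stopping evaluation.
        try:
            df = degrees_of_freedom(data.n_id, n_beta, n_lambda)
            if fit.cov_beta is None:
                stopping = StoppingReport.deferred("no covariance available")
            else:
                S = scale_matrix(fit.cov_beta, df)
                beta_hat_vec = np.array([guess.value(n) for n in guess.estimated_beta])
                sim = sample_fixed_effects(
                    beta_hat_vec, S, df, config.n_stop_sim,
                    _cohort_seed(config, replicate, k, 3),
                )
                stopping = evaluate_stopping(
                    sim,
                    guess.estimated_beta,
                    guess,
                    design,
                    config.band,
                    config.ci_level,
                    df=df,
                )
        except (TooFewSubjectsError, StoppingDeferred) as exc:
            stopping = StoppingReport.deferred(str(exc))

        cohorts.append(
            CohortRecord(
                index=k,
                chosen_dose=chosen_dose,
                criterion_value=crit_value,
                fit=fit,
                stopping=stopping,
                cumulative_design=design,
                fim_true_logdet=fim_true.logdet(),
                fim_true=fim_true,
                optimization_trace=trace,
            )
        )
        logger.info(
            "replicate %d cohort %d: dose=%s ofv=%.2f stop=%s",
            replicate, k, chosen_dose, fit.ofv, stopping.stop,
        )
        if stopping.stop:
            status = "stopped"
            break

    return TrialHistory(
        config=config, replicate=replicate, cohorts=cohorts, status=status, data=data
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_history(history: TrialHistory, path) -> None:
    """Persist a replicate as a directory of YAML/JSON/CSV files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    history.config.save(path / "config.yaml")
    if history.data is not None:
        history.data.to_csv(path / "data.csv")
    log_lines = [
        f"replicate {history.replicate}: {history.status} after "
        f"{history.n_cohorts} cohorts, {history.total_n_id} subjects"
    ] + [
        f"cohort {rec.index}: dose={rec.chosen_dose} "
        f"ofv={rec.fit.ofv:.3f} converged={rec.fit.converged} "
        f"stop={rec.stopping.stop}"
        for rec in history.cohorts
    ]
    (path / "run.log").write_text("\n".join(log_lines) + "\n")
    (path / "status.json").write_text(
        json.dumps(
            {
                "replicate": history.replicate,
                "status": history.status,
                "n_cohorts": history.n_cohorts,
                "total_n_id": history.total_n_id,
            },
            indent=2,
        )
    )
    for rec in history.cohorts:
        stem = path / f"cohort_{rec.index:03d}"
        payload = {
            "index": rec.index,
            "chosen_dose": rec.chosen_dose,
            "criterion_value": rec.criterion_value,
            "cumulative_design": rec.cumulative_design.as_dict(),
            "fim_true_logdet": rec.fim_true_logdet,
            "fit": json.loads(rec.fit.to_json()),
            "stopping": {
                "stop": rec.stopping.stop,
                "df": None if np.isnan(rec.stopping.df) else rec.stopping.df,
                "n_sim": rec.stopping.n_sim,
                "evaluated": rec.stopping.evaluated,
                "reason": rec.stopping.reason,
                "table": rec.stopping.table.to_dict(orient="list"),
            },
        }
        stem.with_suffix(".json").write_text(json.dumps(payload, indent=2))
        rec.fim_true.to_csv(stem.with_name(stem.name + "_fim_true.csv"))
        if rec.optimization_trace is not None:
            rec.optimization_trace.to_csv(
                stem.with_name(stem.name + "_opt_trace.csv"), index=False
            )


def load_history(path) -> TrialHistory:
    """Reload a persisted replicate (fields needed for reporting)."""
    path = Path(path)
    from .config import load_config

    config = load_config(path / "config.yaml")
    status = json.loads((path / "status.json").read_text())
    cohorts = []
    for f in sorted(path.glob("cohort_???.json")):
        d = json.loads(f.read_text())
        stop = d["stopping"]
        cohorts.append(
            CohortRecord(
                index=d["index"],
                chosen_dose=d["chosen_dose"],
                criterion_value=d["criterion_value"],
                fit=EstimationResult.from_json(json.dumps(d["fit"])),
                stopping=StoppingReport(
                    stop=stop["stop"],
                    table=pd.DataFrame(stop["table"]),
                    df=float("nan") if stop["df"] is None else stop["df"],
                    n_sim=stop["n_sim"],
                    evaluated=stop["evaluated"],
                    reason=stop["reason"],
                ),
                cumulative_design=StudyDesign.from_dict(d["cumulative_design"]),
                fim_true_logdet=d["fim_true_logdet"],
                fim_true=FisherMatrix.from_csv(f.with_name(f.stem + "_fim_true.csv")),
            )
        )
    data = TrialDataset.from_csv(path / "data.csv") if (path / "data.csv").exists() else None
    return TrialHistory(
        config=config,
        replicate=status["replicate"],
        cohorts=cohorts,
        status=status["status"],
        data=data,
    )
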