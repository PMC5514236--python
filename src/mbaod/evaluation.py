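"""Post-hoc comparison of adaptive designs against the true-parameter optimum.

The reference trajectory is the theoretically best design: a cohort-wise
lnD-optimization run at the *true* parameters with no estimation or
updating. Each replicate's cumulative design is scored against the
reference cumulative design of the same cohort by the per-parameter
determinant ratio

    efficiency = (|FIM(Θ_true, ξ_test)| / |FIM(Θ_true, ξ_ref)|)^{1/P}

with both FIMs (block-diagonal form) evaluated at the true parameters.
Replicate batches are summarized by per-cohort efficiency percentiles
(2.5/50/97.5), the total-sample-size distribution, a histogram of the
optimized dose selections, and the relative estimation error of the final
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import MBAODConfig
from .design import optimize_next_dose
from .fim import FisherMatrix, population_fim
from .model import GroupDesign, StudyDesign
from .trial import TrialHistory


def design_efficiency(fim_test, fim_ref, p: int | None = None) -> float:
    """Per-parameter determinant ratio (|F_test|/|F_ref|)^{1/p}.

    Accepts :class:`~mbaod.fim.FisherMatrix` or plain arrays. ``p`` defaults
    to the matrix dimension. A singular reference is an error; a singular
    test matrix yields efficiency 0.
    """
    A = fim_test.values if isinstance(fim_test, FisherMatrix) else np.asarray(fim_test)
    B = fim_ref.values if isinstance(fim_ref, FisherMatrix) else np.asarray(fim_ref)
    if A.shape != B.shape:
        raise ValueError(f"matrix shapes differ: {A.shape} vs {B.shape}")
    if p is None:
        p = A.shape[0]
    sign_ref, ld_ref = np.linalg.slogdet(B)
    if sign_ref <= 0 or not np.isfinite(ld_ref):
        raise np.linalg.LinAlgError("reference FIM is singular or indefinite")
    sign_test, ld_test = np.linalg.slogdet(A)
    if sign_test <= 0 or not np.isfinite(ld_test):
        return 0.0
    return float(np.exp((ld_test - ld_ref) / p))


def relative_estimation_error(estimate: float, true: float) -> float:
    """REE = (estimate − true)/true."""
    if true == 0:
        raise ZeroDivisionError("REE undefined for a zero true value")
    return (estimate - true) / true


@dataclass
class ReferenceCohort:
    index: int
    design: StudyDesign
    fim: FisherMatrix
    chosen_dose: int | None


def reference_trajectory(config: MBAODConfig) -> list[ReferenceCohort]:
    """Cohort-wise lnD-optimal designs at the true parameters.

    Cohort 1 is the fixed initial design; each later cohort adds the
    exhaustively lnD-optimal dose at Θ_true. Deterministic (no simulation,
    no estimation, no prior updating).
    """
    theta = config.theta_true
    design = config.initial_design
    out = [
        ReferenceCohort(
            1, design, population_fim(theta, design, form="block_diag"), None
        )
    ]
    for k in range(2, config.max_cohorts + 1):
        opt = optimize_next_dose(
            "lnD", theta, design, config.cohort_group_n, config.dose_grid, times=config.times
        )
        design = design.add_group(GroupDesign(opt.dose, config.cohort_group_n, config.times))
        out.append(
            ReferenceCohort(
                k, design, population_fim(theta, design, form="block_diag"), opt.dose
            )
        )
    return out


@dataclass
class EfficiencyTrace:
    """Per-cohort efficiency of one replicate against the reference."""

    replicate: int
    table: pd.DataFrame  # columns: cohort, efficiency, carried


def efficiency_trace(
    history: TrialHistory,
    reference: Sequence[ReferenceCohort],
    *,
    carry_forward: bool = True,
) -> EfficiencyTrace:
    """Efficiency of a replicate's cumulative designs, cohort by cohort.

    If the replicate stopped before the last reference cohort and
    ``carry_forward`` is set, its final design is scored against the later
    reference cohorts too (flagged in the ``carried`` column).
    """
    p = len(history.config.theta_true.estimated)
    rows = []
    n_obs = history.n_cohorts
    horizon = len(reference) if carry_forward else n_obs
    for k in range(1, horizon + 1):
        rec = history.cohorts[min(k, n_obs) - 1]
        eff = design_efficiency(rec.fim_true, reference[k - 1].fim, p)
        rows.append((k, eff, k > n_obs))
    return EfficiencyTrace(
        replicate=history.replicate,
        table=pd.DataFrame(rows, columns=["cohort", "efficiency", "carried"]),
    )


@dataclass
class ReplicateSummary:
    """Aggregate view over a batch of replicates with a shared config."""

    efficiency: pd.DataFrame  # cohort, p2.5, p50, p97.5, n_replicates
    sample_sizes: pd.DataFrame  # replicate, n_cohorts, total_n_id, status
    dose_histogram: pd.DataFrame  # dose, count, reference_count
    ree: pd.DataFrame  # replicate, parameter, ree
    traces: list[EfficiencyTrace] = field(repr=False, default_factory=list)


def summarize_replicates(
    histories: Sequence[TrialHistory],
    config: MBAODConfig | None = None,
    *,
    reference: Sequence[ReferenceCohort] | None = None,
    carry_forward: bool = True,
) -> ReplicateSummary:
    """Build the replicate summary (efficiency percentiles, sizes, doses, REE)."""
    if len(histories) == 0:
        raise ValueError("need at least one trial history")
    config = config or histories[0].config
    for h in histories:
        if h.config.to_dict() != config.to_dict():
            raise ValueError("histories were run under different configurations")
    if reference is None:
        reference = reference_trajectory(config)

    traces = [efficiency_trace(h, reference, carry_forward=carry_forward) for h in histories]
    eff_long = pd.concat(
        [t.table.assign(replicate=t.replicate) for t in traces], ignore_index=True
    )
    eff = (
        eff_long.groupby("cohort")["efficiency"]
        .agg(**{"p2.5": lambda s: s.quantile(0.025), "p50": "median",
                "p97.5": lambda s: s.quantile(0.975), "n_replicates": "size"})
        .reset_index()
    )

    sizes = pd.DataFrame(
        [
            (h.replicate, h.n_cohorts, h.total_n_id, h.status)
            for h in histories
        ],
        columns=["replicate", "n_cohorts", "total_n_id", "status"],
    )

    # Optimized dose selections only (the fixed cohort-1 arms are excluded);
    # the reference counts match each replicate's realized cohort count.
    chosen = [d for h in histories for d in h.chosen_doses()]
    ref_chosen = [
        reference[k - 1].chosen_dose
        for h in histories
        for k in range(2, h.n_cohorts + 1)
    ]
    doses = sorted(set(chosen) | set(d for d in ref_chosen if d is not None))
    hist = pd.DataFrame(
        {
            "dose": doses,
            "count": [chosen.count(d) for d in doses],
            "reference_count": [ref_chosen.count(d) for d in doses],
        }
    )

    theta_true = config.theta_true
    ree_rows = []
    for h in histories:
        fit = h.final_fit
        for name in theta_true.estimated:
            ree_rows.append(
                (
                    h.replicate,
                    name,
                    relative_estimation_error(fit.theta_hat.value(name), theta_true.value(name)),
                )
            )
    ree = pd.DataFrame(ree_rows, columns=["replicate", "parameter", "ree"])

    return ReplicateSummary(
        efficiency=eff, sample_sizes=sizes, dose_histogram=hist, ree=ree, traces=traces
    )
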