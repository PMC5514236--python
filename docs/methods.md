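# Methods

`mbaod` simulates model-based adaptive optimal design (MBAOD) of a
dose-finding trial: cohorts of subjects are enrolled sequentially, each new
cohort's dose is chosen by maximizing a Fisher-information criterion under
the current parameter knowledge, and the trial stops once the predicted
typical-effect curve is known precisely enough. Everything — data
simulation, information computation, dose optimization, estimation,
stopping — is computed inside the package; there are no external modelling
tools in the loop.

## Model

The response is a sigmoidal EMAX pharmacodynamic model driven by a
one-compartment, first-order absorption oral PK with warfarin-like
parameters:

    C(t)  = D·ka / (V·ka − CL) · (e^{−(CL/V)t} − e^{−ka·t})
    E(C)  = Base + C^γ·EMAX / (C^γ + EC50^γ)
    y     = E(C_i)·(1 + ε_prop) + ε_add

Individual parameters are log-normal around the typical values,
θ_i = β·exp(η_i), with diagonal between-subject variances on EMAX, EC50, CL
and V. `0^γ` is defined as its γ>0 limit 0, so the placebo arm responds at
baseline exactly. Negative simulated observations are retained untouched.
The form `D·ka/(V·ka − CL)` is algebraically identical to the textbook
elimination-rate parameterization with ke = CL/V (a unit test asserts the
identity to machine precision); the removable singularity at ka = ke is
outside the model's contract and raises a degenerate-model error.

### Study scenario

True values: CL 0.15 L/h, V 8 L, ka 1 1/h (all fixed/known), Base 1,
EMAX 100, EC50 7 mg/L, γ 2; ω²(CL, V, EMAX, EC50) = 0.07, 0.02, 0.0625,
0.0625; σ²_add 0.001, σ²_prop 0.015. The design stage and estimation treat
the PK parameters, ω²_CL, ω²_V and σ²_add as known; the seven estimated
parameters are Base, EMAX, EC50, γ, ω²_EMAX, ω²_EC50, σ²_prop. The initial
parameter guess overshoots all four PD fixed effects by +50% (1.5, 150,
10.5, 3). Schedules: sparse t = (0.5, 3, 60) h or rich t = (0.5, 2, 3, 6,
24, 36, 72, 120) h, fixed for all subjects. Cohort 1 is two fixed groups
(0 and 160 mg, four subjects each); every later cohort adds one group of
two subjects at an optimized integer dose in 0–500 mg.

## Fisher information (FO)

The mixed-effects model is linearized at η = 0, ε = 0:
E(y) ≈ f(β, 0), V(y) ≈ L Ω Lᵀ + diag(σ²_prop f² + σ²_add) with
L = ∂f/∂η|₀. The per-subject information over the estimated parameters is
assembled in block-diagonal form (the default, and the form the design
criteria maximize):

    FIM = [[ (∂E/∂β)ᵀ V⁻¹ (∂E/∂β) ,  0 ],
           [ 0 ,  ½·tr(V⁻¹ ∂V/∂λ_a V⁻¹ ∂V/∂λ_b) ]]

A full form adds the β-derivatives of V (including the dependence of the
proportional-error variance on the prediction) to the β block and the mixed
β/λ trace terms as off-diagonal blocks, ½·tr(V⁻¹ ∂V/∂β_j V⁻¹ ∂V/∂λ_l).
The mixed form of the off-diagonal block is the standard Gaussian
information expression; it is validated against a Monte-Carlo estimate of
the expected negative Hessian of the FO log-likelihood (1e5 simulated
response vectors, common random numbers). The population FIM is the
group-size-weighted sum of per-subject FIMs.

All parameter derivatives use central finite differences, relative step
1e-5 with an absolute floor of 1e-8 (the η-Jacobian uses step 1e-5 on the
dimensionless η). Fixed parameters are excluded from differentiation
entirely, never zeroed out. The test oracle re-implements the whole chain
with its own arithmetic at a coarser step (1e-4), giving ~1e-8 relative
agreement for this smooth model.

## Design criteria and dose optimization

* **lnD**: ln|FIM^block-diag(Θ, ξ)| at a point guess; a singular FIM maps
  to a −inf sentinel so the optimizer simply avoids it.
* **ELD** (API): the expectation of the lnD objective over an independent
  normal prior on the estimated fixed effects, approximated by a 10-point
  Latin hypercube sample (one draw per equal-probability stratum per
  dimension, strata paired by random permutation). Non-positive draws are
  redrawn within their stratum because the structural model requires
  positive parameters; the event is logged. With all prior SDs at zero the
  ELD objective equals lnD at the mean (asserted in tests down to 1e-6
  relative SD).

The next cohort's dose is the only free design variable, a discrete
covariate on the 0–500 mg integer grid, so optimization is an exhaustive
scan: every candidate dose's elementary FIM is computed in one vectorized
batch, added to the (fixed) FIM of the accumulated design, and the argmax
taken. Ties break toward the lowest dose, and the same LHS draws are reused
across all candidates (common random numbers), which removes sampling noise
from the comparison between doses. The scan trace (dose → objective) is
stored with the result and persisted per cohort for audit.

## Estimation

Estimation is implemented in-package (no external modelling software is
involved), with two approximate marginal likelihoods:

* **FO**: the Gaussian −2·log-likelihood of the FO moments. All subjects of
  a dose group share E and V, so the objective is a handful of small
  Cholesky factorizations regardless of n.
* **FOCEI**: per-subject empirical-Bayes modes η̂_i found by a damped,
  batched Gauss–Newton (all subjects advance simultaneously; the gradient
  includes the interaction term from the η-dependent residual variance),
  then the standard linearized marginal likelihood expanded at η̂_i with the
  residual variance at the conditional prediction.

The outer optimization runs on transformed parameters (log scale except the
baseline, which may be negative in principle) in three stages: a
derivative-free Nelder–Mead pass on the fast FO surface to find the right
basin — a quasi-Newton line search started from a badly misspecified guess
can overshoot into a spurious flat-dose-response mode (EC50 → 0 or
EMAX·ω² → ∞) that the simplex avoids — then an L-BFGS-B polish of the
requested objective. Finite-difference steps (1e-4) are chosen above the
~1e-6-relative noise left by the warm-started inner optimization. Fits that
stall at the numerical noise floor after real progress are accepted;
attempts that pin a fixed effect at its search box are treated as spurious
modes and retried (up to 3 retries from 10% jittered initials, seeded). A
failed fit is returned with `converged=False` rather than raised, and the
adaptive loop then keeps its previous parameter guess.

`COV_β̂` is the β sub-block — extracted after full inversion — of the
inverse observed information, computed by central differences of the
−log-likelihood on the transformed scale and mapped back by the delta
method. For FOCEI the Hessian step is 2e-2 so the differences dominate
inner-optimization noise. A non-PD Hessian is repaired by clipping its
eigenvalues at 1e-10 and the result flagged; repairs coincide with fits
whose parameters are effectively unidentified from the accumulated data, so
the repaired diagonal is typically enormous.

A calibration test confirms that the model-based covariance matches the
empirical sampling variance of the estimator within a factor 1.5 (FO at 5%
CV between-subject variability, 100 replicates of n = 100; ratios observed
1.01–1.13). At the scenario's 25% CV the FO estimates of EC50 and γ carry a
linearization bias that inflates their empirical spread several-fold beyond
the information bound — a known property of FO and one reason FOCEI is the
trial-loop default.

## Adaptive loop

Per cohort: optimize the new dose (cohort 1 is fixed) → simulate the new
subjects at the true parameters → re-fit all accumulated data starting from
the current guess → evaluate the stopping rule → update the guess and the
ELD prior. The guess update replaces estimated entries by their estimates;
FIX entries never move. The prior update sets SD_j = sqrt(diag COV_β̂) when the
covariance step succeeded cleanly; a repaired (eigenvalue-clipped) or
absent covariance keeps the previous SDs and moves only the mean — a failed
covariance step usually means the fit sits on an unidentified ridge, and
its clipped diagonal (often 1e6 and larger) would turn the prior into noise
rather than a hedge. The first cohort's prior (before any estimation
exists) uses a 10% coefficient of variation around the initial guess. A
frozen-prior mode (`update_priors=False`) keeps the SDs fixed while the
location tracks the current guess; with zero SDs it makes an ELD run replay
the corresponding lnD run exactly, a property used as a consistency test.

**Stopping rule.** With n_ID cumulative subjects, df = n_ID − (n_β̂ +
n_λ̂/2) (2.5 after cohort 1 in this scenario, growing by 2 per cohort), and
scale matrix S = COV_β̂·(df−2)/df, 100,000 fixed-effect vectors are drawn
from a multivariate Student-t located at β̂ — the (df−2)/df factor makes the
draw covariance equal COV_β̂ (checked by simulation at 1e6 draws). Each
draw's typical-individual (η = 0) response is evaluated at every sampling
time of every dose arm enrolled so far; the trial stops when every
empirical 95% CI lies inside 60–140% of the reference response. Choices
within this rule: the reference is the prediction at β̂ (the truth is
unknown to a running trial; the per-point reference is logged so the
alternative is recomputable); the band check is a closed interval; the
placebo arm is included (its reference is the baseline, safely away from
zero, and a near-zero reference auto-fails the point); draws with
non-positive EC50 or γ — possible at low df — give NaN predictions and are
excluded from the quantiles with a logged count; df ≤ 2 (impossible in the
default scenario) defers evaluation to the next cohort.

**Seeding.** Every random stream derives from
(master seed, replicate, cohort, purpose) with purposes (LHS, data
simulation, estimation jitter, stopping draws), and data simulation spawns
one stream per subject. Replicates are therefore independent and bitwise
reproducible, and extending a trial never perturbs earlier cohorts' data.

## Evaluation

The reference ("theoretically best") design is a cohort-wise lnD
optimization at the true parameters with no estimation or updating — fully
deterministic. Each replicate's cumulative design is scored per cohort by

    efficiency = (|FIM(Θ_true, ξ_replicate)| / |FIM(Θ_true, ξ_reference)|)^{1/P}

with P = 7 and block-diagonal FIMs on both sides. Replicates that stop
early carry their final design forward into later-cohort percentiles
(flagged per row; a survivors-only mode is available). Summaries: per-cohort
2.5/50/97.5 efficiency percentiles, the total-sample-size distribution, a
histogram of optimized dose selections with the reference selections
matched to each replicate's realized cohort count (cohort-1's fixed 0/160 mg
arms are not counted), and the per-parameter relative estimation error
(estimate − true)/true of the final fits.

## Problem sizes and defaults

Full-scale settings (50 replicates, up to 50 cohorts, 100,000 stopping
draws) are the config defaults. The test suite and the acceptance script
run desk-scale versions of the same study — 10 and 8 replicates per
criterion, at most 10 and 8 cohorts, 5,000 stopping draws — sized so a full
run completes on a single CPU in minutes. At 5,000 draws the 2.5%/97.5%
empirical quantiles carry a relative standard error of roughly
sqrt(p(1−p)/n)/density ≈ 1–2% of the CI width, well inside the 60–140%
band's resolution.

## What the synthetic data does and does not emulate

The generator draws exactly from the model the estimator assumes — the same
structural PKPD model, log-normal random effects, combined residual error,
no model misspecification (only the +50% initial parameter
misspecification). Passing tests therefore demonstrate the adaptive
machinery under a correctly specified model; they say nothing about
robustness to structural misspecification, dropout, covariates,
inter-occasion variability or non-normal random effects, none of which are
modelled. Stopping behaviour, dose selections and efficiencies in real
trials will differ accordingly.

## Known limitations

* FO information and FO/FOCEI estimation only; no SAEM, no higher-order
  FIM linearizations, no A/E/Ds-optimality, no sampling-time optimization.
* The likelihood surface at cohort-1 sample sizes (8 subjects, 3 sparse
  times, 7 parameters) is genuinely multimodal; the staged optimizer
  recovers the global mode in the cases exercised by the tests, but single
  cohort-1 fits can remain wildly uncertain — which the adaptive loop is
  designed to absorb.
* The stopping rule can fire after the very first cohort when a lucky fit
  is tight; no minimum-information gate is imposed beyond df > 2. In
  replicate batches this places a shared efficiency floor (the carried
  initial design) in the lower tail of both criteria's per-cohort
  distributions, which compresses dispersion-based contrasts between lnD
  and ELD relative to batches in which every replicate adapts at least
  once.
* Estimation accuracy is bounded by the outer optimizer's tolerance
  (~1e-9 relative on the objective, ~1e-4 on parameters).
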