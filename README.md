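# mbaod — model-based adaptive optimal design for dose finding

`mbaod` is a self-contained simulator of **model-based adaptive optimal
design (MBAOD)** for pharmacokinetic–pharmacodynamic dose-optimization
trials. It is aimed at pharmacometricians and trial methodologists who want
to study how adaptive, Fisher-information-driven dose selection behaves
when the design stage starts from misspecified parameter guesses — and in
particular whether a *robust* design criterion buys anything over a *local*
one.

The simulated study: a sigmoidal EMAX effect driven by one-compartment
oral PK (warfarin-like parameters, PK fixed and known), with the four PD
fixed effects (Base, EMAX, EC50, γ) initially overestimated by +50%.
Cohort 1 enrolls two fixed groups (0 and 160 mg, 4 subjects each); each
later cohort adds 2 subjects at an integer dose in 0–500 mg chosen by
maximizing, over an exhaustive grid scan,

* **lnD**: ln |FIM(Θ̂, ξ)| at the current point estimate, or
* **ELD** (API): E_Θ [ ln |FIM(Θ, ξ)| ] over a normal prior on the fixed
  effects (10-point Latin hypercube), whose SDs come from the estimation
  covariance of all previous cohorts,

where FIM is the block-diagonal first-order (FO) population Fisher
information of the nonlinear mixed-effects model. After each cohort the
model is re-fit to all accumulated data by the package's own FO/FOCEI
maximum-likelihood estimator, and the trial stops when 100,000
multivariate-t draws of the fixed effects (location β̂, scale
COV_β̂·(df−2)/df, df = n_ID − n_β̂ − n_λ̂/2) yield 95% CIs of the typical
effect prediction inside 60–140% of the point prediction at every dose and
sampling time. Completed designs are scored against the deterministic
lnD-optimal design at the *true* parameters via the per-parameter
determinant ratio `(|FIM_test|/|FIM_ref|)^(1/P)`.

## Worked example

```python
import mbaod
from mbaod.config import default_config
from mbaod.evaluation import reference_trajectory, efficiency_trace

cfg = default_config(criterion="ELD", max_cohorts=6, n_stop_sim=5000, seed=99)
history = mbaod.run_mbaod(cfg, replicate=0)
print(history.status, history.total_n_id, history.chosen_doses())

ref = reference_trajectory(cfg)
trace = efficiency_trace(history, ref)
print(trace.table.round(3))
```

prints

```
stopped 18 [39, 500, 22, 500, 23]
   cohort  efficiency  carried
0       1       1.000    False
1       2       0.969    False
2       3       0.949    False
3       4       0.987    False
4       5       0.974    False
5       6       0.989    False
```

Reading: this replicate reached the effect-prediction stopping rule after
6 cohorts (18 subjects). Its five optimized doses alternate between a low
dose in the 20–40 mg range — concentrations around EC50, which pin down
EC50 and γ — and the 500 mg cap, the same support points the
true-parameter optimal design uses. The per-parameter determinant-ratio
efficiency accordingly stays at 0.95–0.99 against the theoretically best
design of the same size at every cohort: despite starting with all PD
parameters 50% wrong, the adaptive design loses only a few percent of the
attainable information. (Rows would be flagged `carried` if the replicate
had stopped before the last reference cohort; this one adapted throughout.)

The same machinery is scriptable from a shell:

```bash
mbaod run --replicates 10 --criterion lnD --schedule sparse --seed 1 --out runs/lnd
mbaod report runs/lnd --out report --plots
```

## Layout

| module | contents |
|---|---|
| `mbaod.model` | PK/PD response, designs, trial-data simulation |
| `mbaod.fim` | FO moments, elementary/population Fisher information |
| `mbaod.design` | lnD/ELD objectives, LHS, exhaustive dose scan |
| `mbaod.estimation` | FO & FOCEI maximum likelihood, observed-information covariance |
| `mbaod.trial` | adaptive loop, multivariate-t stopping rule, persistence |
| `mbaod.evaluation` | reference trajectory, efficiency, replicate summaries |
| `mbaod.scenario` / `mbaod.config` / `mbaod.cli` | study constants, YAML config, CLI |

See `docs/methods.md` for the model, the information matrix, the estimator
and every numerical choice in detail.
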