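# sepid — separable effects in illness-death models

`sepid` estimates how much of a baseline treatment's effect on mortality is
mediated by an intermediate illness, in the continuous-time irreversible
illness-death model (healthy → ill → dead, with direct healthy → dead
transitions and right censoring). It is written for biostatisticians and
epidemiologists analysing registry or trial data in which the mediator is a
*time-to-event* state that can be truncated by death — a setting where
classical natural direct/indirect effects are ill-defined.

## The estimands and estimators

Treatment `A` is conceptually decomposed into a component `A^I` that affects
death only through illness and a component `A^D` that affects death
directly. With `T2^{a_D, a_I}` the counterfactual death time under separate
interventions on the two components, the targets on a horizon grid τ are

    SDE(τ, a_I) = P(T2^{1,a_I} ≤ τ) − P(T2^{0,a_I} ≤ τ)      (separable direct)
    SIE(τ, a_D) = P(T2^{a_D,1} ≤ τ) − P(T2^{a_D,0} ≤ τ)      (separable indirect)
    TE(τ)       = SDE(τ, a) + SIE(τ, 1−a)                     (total, exactly)

Under exchangeability, positivity, consistency of the decomposition and the
dismissible-components conditions, each counterfactual risk is identified by
a G-computation functional built from the three transition hazards
Λ12, Λ13, Λ23:

    ψ(τ, a_D, a_I) = E_W [ 1 − Ω_τ(W) − ∫₀^τ S2(τ|r, a_D, W) Ω_{r−}(W) dΛ12(r | a_I, W) ],
    Ω_r(W) = exp{ −Λ12(r | a_I, W) − Λ13(r | a_D, W) }.

Two estimators are provided, both using Cox working models with Breslow
baselines (delayed entry for the 2→3 transition) plus a logistic propensity
and Cox censoring models:

* **plug-in (G-computation)** — the empirical average of the functional at
  the fitted hazards; consistent only if all three transition hazard models
  are correct;
* **one-step** — the sample mean of the efficient influence function, which
  augments the plug-in with inverse-probability-weighted martingale residual
  terms for the three transitions. It is multiply robust: consistent when at
  most one transition hazard is misspecified (with correct propensity and
  censoring models), or when only the propensity and censoring models are
  wrong.

Inference is by nonparametric bootstrap (all nuisances refitted per
replicate) with Wald intervals.

## Worked example

```python
import sepid as sp

config = sp.make_scenario(1, "i", n=400, seed=7)      # correctly specified DGP
data = sp.simulate_observed_study1(config)
result = sp.bootstrap_ci(data, tau_grid=[5.0, 15.0, 25.0],
                         estimator="one_step", n_boot=100, seed=1)
print(result.to_frame())
truth, mc_se = sp.true_sde_mc(config, a_i=1, tau=15.0, n_mc=200_000, seed=3)
```

prints (excerpt; `examples/01_simulate_and_estimate.py` is the full script)

```
estimand  tau  level   estimate       se     ci_low  ci_high  estimator
     sde 15.0   aI=1   0.158397 0.072578   0.016147 0.300648   one_step
     sie 15.0   aD=1   0.125892 0.036613   0.054132 0.197652   one_step
      te 15.0          0.257376 0.059913   0.139949 0.374803   one_step

true SDE(tau=15, aI=1) from the counterfactual oracle: +0.1732 (MC se 0.0015)
```

i.e. by τ = 15 the treatment raises 15-unit mortality risk by ≈ 26
percentage points in total, of which ≈ 16 points act directly on death
(SDE) and ≈ 13 through the illness pathway (SIE); the Wald intervals come
from 100 bootstrap refits, and the one-step estimate is compatible with the
Monte-Carlo counterfactual truth. Other entry points: a misspecification /
robustness replication (`examples/02_multiple_robustness.py`), the
unmeasured-common-cause violation study (`examples/03_assumption_violation.py`),
CSV analysis and the `sepid` command line (`examples/04_custom_data.py`).

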