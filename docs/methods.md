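# Methods

## Model and observed data

The package works with the irreversible illness-death process: state 1
(healthy, everyone starts there), state 2 (ill), state 3 (dead, absorbing);
2→1 transitions are excluded. Cause-specific hazards λ12, λ13 act on the
time `T1` of leaving state 1, λ23 on the death time `T2` of ill subjects;
`η = I(T1 < T2)` marks whether illness occurred. Under right censoring by
`C` the observed record is `(T̃1, T̃2, η̃, δ, A, W)` with `T̃j = Tj ∧ C`,
`δ = I(T2 < C)` (an exact tie is resolved event-first so rounded real data
remain usable), a binary baseline treatment `A` and baseline covariates
`W`. Times are on an arbitrary continuous scale with origin at study entry.
Censoring is assumed coarsening-at-random; its state-1 and state-2 hazards
yield the uncensored-probability functions `K1(t|a,w)` and `K2(t|r,a,w)`.

## Estimands and identification

Treatment is decomposed into an illness-path component `A^I` (enters λ12
only) and a direct component `A^D` (enters λ13 and λ23). The estimands are
contrasts of `ψ(τ, a_D, a_I) = P(T2^{a_D,a_I} ≤ τ)`: the separable direct
effect varies `a_D` at fixed `a_I`, the separable indirect effect varies
`a_I` at fixed `a_D`, and their sum telescopes exactly to the total effect.
Identification needs conditional exchangeability given `W`, positivity,
consistency of the decomposition (`A^D = A^I = A` in the observed world)
and the dismissible-components conditions — the counterfactual hazard of
each transition may depend only on its own treatment component. These
assumptions are documented preconditions; the package does not (and cannot)
test them, and the violation study below quantifies what happens when the
last one fails. Under them,

    ψ(τ, a_D, a_I) = E_W[ P13(τ, a_D, a_I, W) ],
    P13 = 1 − Ω_τ − ∫_(0,τ] S2(τ|r, a_D, w) Ω_{r−} dΛ12(r | a_I, w),
    Ω_r = exp{−Λ12(r|a_I, w) − Λ13(r|a_D, w)},

with `S2(t|r,a,w) = exp{−[Λ23(t|a,w) − Λ23(r|a,w)]}` on the study time
scale (Markov-type clock; the time-since-illness clock is out of scope —
for the constant-rate generators both clocks coincide).

## Nuisance models

Five components are fitted, matching the default working models of the
simulation studies: a main-effects logistic propensity (statsmodels MLE,
predictions clipped to [0.01, 0.99], configurable); Cox models with
main effects of treatment and covariates for the three transition hazards
(risk sets: (0, T̃1] for 1→2 and 1→3; left-truncated (T̃1, T̃2] restricted
to η̃=1 for 2→3); covariate-free Cox (Nelson–Aalen) censoring models per
state, a state with no censoring events degenerating to K ≡ 1 with a
warning. The Cox fitter is implemented in the package (Newton–Raphson with
step-halving, Breslow tie handling, Breslow baseline, delayed entry)
because the estimator needs exact access to baseline jump times,
increments and left limits per risk-set convention; it is cross-checked in
the tests against lifelines (tie-free data makes Efron and Breslow
coincide) and reduces exactly to Nelson–Aalen with no covariates.
Treatment must enter unstratified (shared baseline): the EIF's 2→3 weight
contains the ratio λ12(s|a_I,w)/λ12(s|a_D,w), which is only well defined
across arms when the baseline cancels. Beyond the last event time a step
baseline is continued as constant with an `ExtrapolationWarning`.

A closed-form "oracle" nuisance set mirrors the exponential generating
processes exactly (constant rates with log-linear predictors) and is used
to separate identification error from estimation error in the tests. For
study-2 configurations it exists only at `gamma_u = 0`; otherwise the
generating hazards condition on the latent U and are not functions of the
observables.

## Estimators

* Plug-in / G-computation: `n⁻¹ Σ_i P̂13(τ, a_D, a_I, W_i)`.
* One-step: `n⁻¹ Σ_i φ̂_i`, where φ is the observed-data efficient
  influence function: the plug-in term plus, for each transition, an
  inverse-probability-of-treatment and censoring weighted integral of the
  martingale residual against a weight function built from Ω, S2 and the
  Λ12 jump measure. The estimating function is multiply robust: its mean
  stays at ψ when at most one transition hazard (with propensity and
  censoring correct), or only the propensity and censoring pair, is
  misspecified.

Numerical conventions, chosen once and applied consistently:

* all integrals against fitted step hazards are exact finite sums over the
  baseline jump grids — no discretisation tolerance beyond the estimators
  themselves;
* denominators (S1, K1, S2, K2 at jump times, including the 2→3 prefactor
  at T̃1) use predictable left limits; survival factors inside the h
  weights are right-continuous, and tail integrals run over `(s, τ]`,
  which makes `h12(τ) = 0` and `h13(0) = 1 − P13(τ)` exact identities on
  any step nuisance set;
* oracle (smooth) nuisances are integrated by vectorised 64-node
  Gauss–Legendre quadrature; the integrands are products of exponentials,
  for which this is accurate to ~1e-14 (spot-checked against adaptive
  quadrature), and the 2→3 compensator uses a stable `expm1`-based closed
  form;
* positivity guards: any propensity, `S1·K1` or `S2·K2` value that a
  *contributing* subject's term would divide by is floored at 1e-8; a
  breach raises a `PositivityError` naming offending subjects rather than
  silently producing huge weights;
* the one-step equals the plug-in plus the mean martingale correction by
  construction, and `TE − SDE − SIE = 0` holds to machine precision; the
  plug-in risks are monotone in τ and lie in [0, 1], while the one-step
  estimate, being a mean of influence values, is not range-restricted.

Variance is by nonparametric bootstrap (default 250 replicates; the
simulation harness scales this down, see below), refitting every nuisance
per replicate, with Wald intervals by default and percentile intervals
behind a flag. Replicate-level fit failures are logged and skipped, with a
10% failure cap. The stacked-estimating-equation sandwich variance is not
implemented: with nonparametric baselines its functional-delta-method form
is unwieldy, and the bootstrap is the reference approach here.

## Synthetic data generators

Study 1 (estimator performance): `W ~ U(0,1)`;
`A|W ~ Bern(expit(−0.5 + W + ζW²))`; exit from state 1 at rate
`λ12 + λ13` with `λ12 = 0.039·exp(log(2)W + A + γ12·AW)`,
`λ13 = 0.026·exp(log(2)W + 0.5A + γ13(1−A)W)`; illness flag
`η ~ Bern(λ12/(λ12+λ13))`; for ill subjects an additive exponential
sojourn at `λ23 = 0.052·exp(log(2)W + 0.5A + γ23(1−A)W)`; censoring
`C ~ Exp(0.035·e^{θW})`. This mixture construction equals the
competing-exponential construction in distribution (verified in the
tests against analytic sub-distribution functions). With
`(ζ, γ12, γ13, γ23, θ) = 0` every default working model is correctly
specified; each scenario (ii)–(viii) switches a documented subset of knobs
to magnitude 1. The printed `+A` coefficient in λ12 is kept as printed
(treatment raises the illness hazard); it is a config field (`a12`) for
users who want a protective value. A measured caveat: because the fitted
Λ12(·|a_I, w) enters both arms of the SDE contrast, the γ12 interaction
misspecification largely cancels in the SDE — its plug-in bias saturates
near +0.005 for any |γ12| ≤ 3, visible only at replication counts near
1000. The γ13 and γ23 misspecifications produce clearly visible plug-in
bias at 200 replications.

Study 2 (violation): `W ~ Bern(0.5)`, unmeasured `U ~ Bern(0.6)` with
log-hazard-ratio `gamma_u` in all three transition hazards; treatment
components with log-HRs `β12_A` (illness path) and `β13_A` (death path),
sign patterns by case I–IV and default magnitudes 1 and 0.5, matching the
study-1 treatment coefficients. The four-arm world defines the truth (latents retained, fed
only to the truth oracle); the analysed two-arm data set both components
to the same drawn `A` and drop U. The truth oracle is a brute-force
Monte-Carlo draw of the counterfactual world (default 2·10⁵, the
acceptance runs use 10⁶), cross-checked against an exact closed-form
G-computation over (W, U).

What the generators do not emulate: time-varying covariates or treatments,
non-exponential (non-PH) hazards, interval censoring, dependent censoring
beyond covariates, recurrent illness. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Simulation harness and problem sizes

`run_simulation_study` replays the studies: per dataset it fits the default
working models, computes both estimators of the SDE curve (`a_I = 1` by
default) and optionally bootstraps, then aggregates bias (against the MC
truth, whose MC standard error is carried into all bias assessments),
empirical SE, 95% Wald coverage and mean-estimated-SE/empirical-SE. All
randomness flows from a master seed through `SeedSequence`-derived
per-dataset seeds; reruns are bit-identical. The package's replication
sizes are 200 datasets of n = 400 (study 1) or n = 1000 (study 2) with 50
bootstrap replicates where coverage is assessed — enough for ~1.5%
binomial precision on coverage and for 2-SE bias checks at the effect
sizes involved, while keeping a full replication in the minutes range on
one CPU. A consequence, noted above, is that the saturated γ12 plug-in
bias sits below the 2-SE detection threshold at this replication count.

## Known limitations

* Markov (study-time) clock for the 2→3 hazard only.
* Semiparametric working models only; the one-step estimator is compatible
  with data-adaptive nuisance estimators in principle, but none are wired
  in.
* The one-step estimator is noticeably more variable than the plug-in at
  n = 400, consistent with its extra weighting terms.
* Identification rests on the dismissible-components conditions; the
  study-2 harness shows bias growing with the strength of an unmeasured
  common cause, with direction determined by the sign of the treatment
  effect on illness (positive bias when the illness-path effect is
  protective under the two-arm observed design used here).
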