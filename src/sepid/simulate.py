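"""Synthetic data generators for the two simulation studies and a
Monte-Carlo oracle for the true counterfactual risks.

Study 1 (estimator performance): a continuous covariate W ~ Uniform(0,1),
logistic treatment assignment, exponential transition times with log-linear
covariate effects and exponential censoring.  Misspecification knobs
(``zeta``, ``gamma12``, ``gamma13``, ``gamma23``, ``theta``) add terms that the
main-effects working models omit; with all knobs at zero every working model
is correctly specified.

Study 2 (assumption violation): a binary covariate W ~ Bernoulli(0.5) and an
*unmeasured* binary risk factor U ~ Bernoulli(0.6) entering all three
transition hazards with log-hazard-ratio ``gamma_u``, which violates the
dismissible-components conditions whenever ``gamma_u != 0``.  The treatment is
decomposed into a component acting on illness (log-HR ``beta12_a`` in the 1→2
hazard) and a component acting on death (log-HR ``beta13_a`` in the 1→3 and
2→3 hazards); cases I–IV set the signs of the two components.

The latent event pair is generated by the exact mixture construction: draw
T1 from an exponential with the total exit rate, an illness flag with
probability lam12/(lam12+lam13), and for ill subjects an additive
exponential sojourn in the illness state — equal in distribution to the
competing-exponential construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import Dataset, validate_dataset

LOG2 = float(np.log(2.0))

STUDY2_CASES = {
    # (sign of illness-component log-HR, sign of death-component log-HR)
    "I": (-1.0, -1.0),   # protective on disease and death
    "II": (-1.0, +1.0),  # protective on disease, harmful on death
    "III": (+1.0, -1.0),  # harmful on disease, protective on death
    "IV": (+1.0, +1.0),  # harmful on disease and death
}

STUDY1_SCENARIOS = {
    # active misspecification knobs per scenario
    "i": (),
    "ii": ("zeta", "theta"),
    "iii": ("gamma12",),
    "iv": ("gamma13",),
    "v": ("gamma23",),
    "vi": ("gamma12", "gamma13"),
    "vii": ("gamma12", "gamma23"),
    "viii": ("gamma13", "gamma23"),
}


@dataclass
class SimulationConfig:
    """All data-generating rates, coefficients and misspecification knobs.

    Base rates are per unit study time.  ``a12``, ``a13``, ``a23`` are the
    treatment log-hazard-ratios of study 1 (the 1→2 coefficient is kept as
    a field so a protective value such as −1 can be requested).  Study-2
    fields are ignored unless ``case`` is set.
    """

    # study-1 base rates and coefficients
    b12: float = 0.039
    b13: float = 0.026
    b23: float = 0.052
    b_c: float = 0.035
    coef_w: float = LOG2
    a12: float = 1.0
    a13: float = 0.5
    a23: float = 0.5
    # misspecification knobs (study 1)
    zeta: float = 0.0
    gamma12: float = 0.0
    gamma13: float = 0.0
    gamma23: float = 0.0
    theta: float = 0.0
    # violation knobs (study 2)
    case: str | None = None
    gamma_u: float = 0.0
    u_prev: float = 0.6
    beta12_a: float = 1.0  # magnitude of the illness-component effect
    beta13_a: float = 0.5  # magnitude of the death-component effect
    # sampling
    n: int = 400
    seed: int = 0
    covariate_names: list[str] = field(default_factory=lambda: ["w"])

    def __post_init__(self) -> None:
        for name in ("b12", "b13", "b23", "b_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"base rate {name} must be > 0")
        if not (0.0 < self.u_prev < 1.0):
            raise ValueError("u_prev must be in (0, 1)")
        if self.case is not None and self.case not in STUDY2_CASES:
            raise ValueError(f"unknown study-2 case {self.case!r}")
        if self.n <= 0:
            raise ValueError("n must be positive")

    # -- generating hazard rates -----------------------------------------
    def study1_rates(self, a, w):
        """Constant-in-time transition rates (lam12, lam13, lam23) of study 1.

        ``a`` is the value of the treatment component relevant to each
        transition (illness component for 1→2, death component for 1→3 and
        2→3), so these functions also define the counterfactual rates of
        the decomposed-treatment world.
        """
        a = np.asarray(a, float)
        w = np.asarray(w, float)
        lam12 = self.b12 * np.exp(self.coef_w * w + self.a12 * a + self.gamma12 * a * w)
        lam13 = self.b13 * np.exp(self.coef_w * w + self.a13 * a + self.gamma13 * (1 - a) * w)
        lam23 = self.b23 * np.exp(self.coef_w * w + self.a23 * a + self.gamma23 * (1 - a) * w)
        return lam12, lam13, lam23

    def study2_rates(self, a_d, a_i, w, u):
        b12a, b13a = self.study2_coefs()
        base = self.coef_w * np.asarray(w, float) + self.gamma_u * np.asarray(u, float)
        lam12 = self.b12 * np.exp(base + b12a * np.asarray(a_i, float))
        lam13 = self.b13 * np.exp(base + b13a * np.asarray(a_d, float))
        lam23 = self.b23 * np.exp(base + b13a * np.asarray(a_d, float))
        return lam12, lam13, lam23

    def study2_coefs(self) -> tuple[float, float]:
        if self.case is None:
            raise ValueError("study-2 case not set")
        s12, s13 = STUDY2_CASES[self.case]
        return s12 * abs(self.beta12_a), s13 * abs(self.beta13_a)

    def censoring_rate(self, w):
        return self.b_c * np.exp(self.theta * np.asarray(w, float))

    def propensity(self, w):
        w = np.asarray(w, float)
        return expit(-0.5 + w + self.zeta * w**2)


def make_scenario(study: int, scenario_id: str, *, gamma_u: float | None = None,
                  knob: float = 1.0, **overrides) -> SimulationConfig:
    """Build the configuration of a named scenario.

    Study 1: ids "i"–"viii"; every active misspecification knob of the
    scenario is set to ``knob`` (default magnitude 1).  Study 2: ids are the
    cases "I"–"IV" combined with a ``gamma_u`` value from the grid.
    """
    if study == 1:
        if scenario_id not in STUDY1_SCENARIOS:
            raise ValueError(f"unknown study-1 scenario {scenario_id!r}")
        knobs = {name: knob for name in STUDY1_SCENARIOS[scenario_id]}
        return SimulationConfig(**{**knobs, **overrides})
    if study == 2:
        if scenario_id not in STUDY2_CASES:
            raise ValueError(f"unknown study-2 case {scenario_id!r}")
        if gamma_u is None:
            raise ValueError("study-2 scenarios require gamma_u")
        overrides.setdefault("n", 1000)
        return SimulationConfig(case=scenario_id, gamma_u=gamma_u, **overrides)
    raise ValueError(f"unknown study {study!r}")


def _latent_event_times(rng, lam12, lam13, lam23):
    """Mixture construction of (T1, eta, T2) given the three rates."""
    total = lam12 + lam13
    t1 = rng.exponential(1.0 / total)
    eta = (rng.random(t1.shape) < lam12 / total).astype(int)
    sojourn = rng.exponential(1.0 / lam23)
    t2 = t1 + eta * sojourn
    return t1, eta, t2


def _coarsen(t1, eta, t2, c, a, covs: dict) -> Dataset:
    """Apply right censoring and assemble observed records.

    Ties between an event and a censoring time are resolved event-first
    (probability zero under these generators).
    """
    t1_obs = np.minimum(t1, c)
    t2_obs = np.minimum(t2, c)
    death = (t2 <= c).astype(int)
    illness = (t1_obs < t2_obs).astype(int)
    df = pd.DataFrame({
        "time1": t1_obs, "time2": t2_obs, "illness": illness,
        "death": death, "treatment": np.asarray(a, int),
    })
    for name, vals in covs.items():
        df[name] = vals
    return validate_dataset(Dataset(df, list(covs)))


def simulate_observed_study1(config: SimulationConfig) -> Dataset:
    """Observed two-arm data from the study-1 generating process."""
    if config.case is not None:
        raise ValueError("study-1 simulator called with a study-2 case set")
    rng = np.random.default_rng(config.seed)
    w = rng.random(config.n)
    a = (rng.random(config.n) < config.propensity(w)).astype(int)
    lam12, lam13, lam23 = config.study1_rates(a, w)
    t1, eta, t2 = _latent_event_times(rng, lam12, lam13, lam23)
    c = rng.exponential(1.0 / config.censoring_rate(w))
    return _coarsen(t1, eta, t2, c, a, {"w": w})


def simulate_fourarm_study2(config: SimulationConfig, a_d: int, a_i: int) -> pd.DataFrame:
    """Four-arm (decomposed-treatment) world of study 2 with latents retained.

    Returns a DataFrame with the latent event data (``t1``, ``eta``, ``t2``),
    the unmeasured risk factor ``u``, the interventions and the observed,
    censored coarsening.  Not a :class:`Dataset`: the interventions are set
    deterministically so the two-arm data contract does not apply; this
    object feeds the truth oracle only and ``u`` is never exposed to
    estimators.
    """
    if config.case is None:
        raise ValueError("study-2 simulator requires a case (I–IV)")
    rng = np.random.default_rng(config.seed)
    w = (rng.random(config.n) < 0.5).astype(float)
    u = (rng.random(config.n) < config.u_prev).astype(float)
    lam12, lam13, lam23 = config.study2_rates(a_d, a_i, w, u)
    t1, eta, t2 = _latent_event_times(rng, lam12, lam13, lam23)
    c = rng.exponential(1.0 / config.b_c, size=config.n)
    return pd.DataFrame({
        "w": w, "u": u, "a_d": a_d, "a_i": a_i,
        "t1": t1, "eta": eta, "t2": t2, "c": c,
        "time1": np.minimum(t1, c), "time2": np.minimum(t2, c),
        "death": (t2 <= c).astype(int),
    })


def simulate_observed_study2(config: SimulationConfig) -> Dataset:
    """Observed two-arm study-2 data: A drawn from the propensity, both
    treatment components set to A, and the common risk factor U dropped."""
    if config.case is None:
        raise ValueError("study-2 simulator requires a case (I–IV)")
    rng = np.random.default_rng(config.seed)
    w = (rng.random(config.n) < 0.5).astype(float)
    u = (rng.random(config.n) < config.u_prev).astype(float)
    a = (rng.random(config.n) < expit(-0.5 + w)).astype(int)
    lam12, lam13, lam23 = config.study2_rates(a, a, w, u)
    t1, eta, t2 = _latent_event_times(rng, lam12, lam13, lam23)
    c = rng.exponential(1.0 / config.b_c, size=config.n)
    return _coarsen(t1, eta, t2, c, a, {"w": w})


def true_psi_mc(config: SimulationConfig, a_d: int, a_i: int, tau,
                n_mc: int = 200_000, seed: int = 0):
    """Brute-force Monte-Carlo oracle for E{I(T2^{aD,aI} <= tau)}.

    Draws the covariates (and, for study 2, the unmeasured U) and the latent
    uncensored event times under interventions ``(a_d, a_i)`` applied to the
    corresponding treatment components, and returns the frequency of the
    terminal event by ``tau`` with its binomial standard error.  ``tau`` may
    be a scalar or an array (shared draws across the grid).
    """
    rng = np.random.default_rng(seed)
    if config.case is None:
        w = rng.random(n_mc)
        lam12 = config.study1_rates(a_i, w)[0]
        lam13 = config.study1_rates(a_d, w)[1]
        lam23 = config.study1_rates(a_d, w)[2]
    else:
        w = (rng.random(n_mc) < 0.5).astype(float)
        u = (rng.random(n_mc) < config.u_prev).astype(float)
        lam12, lam13, lam23 = config.study2_rates(a_d, a_i, w, u)
    t1, eta, t2 = _latent_event_times(rng, lam12, lam13, lam23)
    tau_arr = np.atleast_1d(np.asarray(tau, float))
    p = np.array([(t2 <= t).mean() for t in tau_arr])
    se = np.sqrt(p * (1 - p) / n_mc)
    if np.isscalar(tau) or np.ndim(tau) == 0:
        return float(p[0]), float(se[0])
    return p, se


def true_sde_mc(config: SimulationConfig, a_i: int, tau, n_mc: int = 200_000,
                seed: int = 0):
    """True separable direct effect psi(tau,1,aI) − psi(tau,0,aI) by MC,
    with the combined Monte-Carlo standard error."""
    p1, se1 = true_psi_mc(config, 1, a_i, tau, n_mc, seed)
    p0, se0 = true_psi_mc(config, 0, a_i, tau, n_mc, seed + 1)
    return p1 - p0, np.hypot(se1, se0)


def derived_seeds(master_seed: int, k: int) -> list[int]:
    """Independent per-task seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(k)]
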