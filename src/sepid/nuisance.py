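"""The five nuisance components consumed by every estimator: the three
transition hazards (1→2, 1→3, 2→3), the censoring survival probabilities in
states 1 and 2, and the treatment propensity.

Two hazard representations share one interface:

* :class:`BreslowHazard` — semiparametric Cox fit with a step-function
  baseline; exposes the jump grid so downstream integrals are exact sums.
* :class:`OracleHazard` — closed-form constant-in-time rate with a
  log-linear predictor, matching the exponential generating processes of the
  simulation studies; has no jump grid and is integrated by quadrature.

The 2→3 hazard is modelled on the study time scale (Markov-type clock) with
left truncation at the illness time, so
``S2(t | r, a, w) = exp{−[Λ23(t|a,w) − Λ23(r|a,w)]}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .cox import CoxError, CoxFit, fit_cox
from .data import Dataset


class PositivityError(RuntimeError):
    """A propensity, survival or censoring probability hit its floor."""


class ExtrapolationWarning(UserWarning):
    """A step-function hazard was evaluated beyond its last jump time."""


# ---------------------------------------------------------------------------
# hazard models
# ---------------------------------------------------------------------------

class _HazardBase:
    delayed_entry: bool = False

    def multiplier(self, a, W) -> np.ndarray:
        """exp(linear predictor) for treatment value ``a`` and covariates W."""
        raise NotImplementedError

    def base_cumhaz(self, t, *, left: bool = False):
        raise NotImplementedError

    def cumhaz(self, t, a, W, entry=None, *, left: bool = False) -> np.ndarray:
        """Λ(t | a, w) (or its left limit); with delayed entry the increment
        Λ(t) − Λ(entry) is returned."""
        base = self.base_cumhaz(t, left=left)
        if self.delayed_entry:
            if entry is None:
                raise ValueError("delayed-entry hazard requires an entry time")
            base = base - self.base_cumhaz(entry)
        return base * self.multiplier(a, W)


@dataclass
class BreslowHazard(_HazardBase):
    """Cox fit with Breslow baseline on a jump grid.

    ``covariates`` are covariate column labels and ``with_treatment``
    indicates whether treatment enters the (shared-baseline) linear
    predictor; treatment-by-covariate interactions may be added as
    ``interactions`` (covariate labels).
    """

    fit: CoxFit
    covariates: list[str]
    with_treatment: bool
    interactions: list[str] = field(default_factory=list)
    cov_index: dict = field(default_factory=dict)
    delayed_entry: bool = False
    warn_extrapolate: bool = True

    def __post_init__(self):
        self._cum = np.concatenate([[0.0], np.cumsum(self.fit.base_increments)])

    @property
    def jump_times(self) -> np.ndarray:
        return self.fit.jump_times

    @property
    def base_increments(self) -> np.ndarray:
        return self.fit.base_increments

    def design(self, a, W) -> np.ndarray:
        W = np.atleast_2d(np.asarray(W, float))
        n = W.shape[0]
        cols = []
        if self.with_treatment:
            cols.append(np.full(n, float(a)))
        for c in self.covariates:
            cols.append(W[:, self.cov_index[c]])
        for c in self.interactions:
            cols.append(float(a) * W[:, self.cov_index[c]])
        if not cols:
            return np.empty((n, 0))
        return np.column_stack(cols)

    def multiplier(self, a, W) -> np.ndarray:
        X = self.design(a, W)
        if X.shape[1] == 0:
            return np.ones(X.shape[0])
        return np.exp(X @ self.fit.beta)

    def base_cumhaz(self, t, *, left: bool = False):
        t = np.asarray(t, float)
        if self.warn_extrapolate and np.any(t > self.jump_times[-1]):
            warnings.warn(
                "cumulative hazard evaluated beyond the last event time; "
                "extrapolating as constant", ExtrapolationWarning, stacklevel=2)
        side = "left" if left else "right"
        return self._cum[np.searchsorted(self.jump_times, t, side=side)]


@dataclass
class OracleHazard(_HazardBase):
    """Constant-in-time rate ``base_rate * exp(lp(a, w))`` in closed form."""

    base_rate: float
    lp: Callable  # (a, W[n,d]) -> (n,) log relative rate
    delayed_entry: bool = False

    def multiplier(self, a, W) -> np.ndarray:
        W = np.atleast_2d(np.asarray(W, float))
        return np.exp(np.asarray(self.lp(a, W), float))

    def rate(self, a, W) -> np.ndarray:
        return self.base_rate * self.multiplier(a, W)

    def base_cumhaz(self, t, *, left: bool = False):
        return self.base_rate * np.asarray(t, float)

    @property
    def jump_times(self):
        return None


def hazard_ratio_12(model: _HazardBase, s, a_i: int, a_d: int, W) -> np.ndarray:
    """λ12(s | aI, w) / λ12(s | aD, w) from a shared-baseline model.

    The baseline cancels, so the ratio is time-constant for the
    proportional-hazards forms used here (``s`` is accepted for interface
    symmetry).
    """
    return model.multiplier(a_i, W) / model.multiplier(a_d, W)


# ---------------------------------------------------------------------------
# censoring and propensity
# ---------------------------------------------------------------------------

@dataclass
class CensoringModel:
    """K1/K2: probabilities of remaining uncensored in states 1 and 2.

    Either hazard may be None, meaning no censoring was observed in that
    state and K ≡ 1.
    """

    state1: _HazardBase | None
    state2: _HazardBase | None

    def K1(self, t, a, W, *, left: bool = False) -> np.ndarray:
        if self.state1 is None:
            n = np.atleast_2d(np.asarray(W, float)).shape[0]
            return np.ones(np.broadcast_shapes(np.shape(t), (n,)))
        return np.exp(-self.state1.cumhaz(t, a, W, left=left))

    def K2(self, t, entry, a, W, *, left: bool = False) -> np.ndarray:
        if self.state2 is None:
            n = np.atleast_2d(np.asarray(W, float)).shape[0]
            return np.ones(np.broadcast_shapes(np.shape(t), np.shape(entry), (n,)))
        return np.exp(-self.state2.cumhaz(t, a, W, entry=entry, left=left))


@dataclass
class PropensityModel:
    """Logistic regression of treatment on covariates, with clipping."""

    beta: np.ndarray          # intercept first
    covariates: list[str]
    cov_index: dict
    clip: float = 0.01
    se: np.ndarray | None = None

    def prob(self, a, W) -> np.ndarray:
        """π(a | w), clipped to [clip, 1−clip]."""
        W = np.atleast_2d(np.asarray(W, float))
        cols = [np.ones(W.shape[0])] + [W[:, self.cov_index[c]] for c in self.covariates]
        p1 = expit(np.column_stack(cols) @ self.beta)
        p1 = np.clip(p1, self.clip, 1.0 - self.clip)
        return p1 if a == 1 else 1.0 - p1


@dataclass
class OraclePropensity:
    fn: Callable  # W[n,d] -> P(A=1 | w)
    clip: float = 0.0

    def prob(self, a, W) -> np.ndarray:
        W = np.atleast_2d(np.asarray(W, float))
        p1 = np.asarray(self.fn(W), float)
        if self.clip:
            p1 = np.clip(p1, self.clip, 1 - self.clip)
        return p1 if a == 1 else 1.0 - p1


@dataclass
class NuisanceSet:
    """The five fitted (or oracle) components used by every estimator."""

    lambda12: _HazardBase
    lambda13: _HazardBase
    lambda23: _HazardBase
    censoring: CensoringModel
    propensity: PropensityModel | OraclePropensity
    provenance: str = "fitted"

    @property
    def is_oracle(self) -> bool:
        return self.lambda12.jump_times is None


# ---------------------------------------------------------------------------
# fitting from data
# ---------------------------------------------------------------------------

def _check_both_arms(a: np.ndarray) -> None:
    if a.min() == a.max():
        raise PositivityError(
            "only one treatment arm present; propensity and hazard models "
            "require both arms (positivity)")


def fit_propensity(data: Dataset, covariates: Sequence[str] | None = None,
                   clip: float = 0.01) -> PropensityModel:
    """Maximum-likelihood logistic regression of treatment on covariates."""
    a = data.treatment
    _check_both_arms(a)
    covs = list(data.covariates if covariates is None else covariates)
    cov_index = {c: i for i, c in enumerate(data.covariates)}
    X = sm.add_constant(data.W[:, [cov_index[c] for c in covs]], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(a, X).fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
        raise PositivityError(
            "propensity fit did not converge (perfect separation?); consider "
            "clipping or penalisation")
    return PropensityModel(beta=np.asarray(res.params), covariates=covs,
                           cov_index=cov_index, clip=clip,
                           se=np.asarray(res.bse))


_TRANSITIONS = {12, 13, 23}


def fit_transition_cox(data: Dataset, transition: int,
                       covariates: Sequence[str] | None = None,
                       interactions: Sequence[str] = (),
                       with_treatment: bool = True) -> BreslowHazard:
    """Cox fit for one transition with the appropriate risk sets.

    1→2: interval (0, t1] with event = observed illness; 1→3: interval
    (0, t1] with event = direct death; 2→3: ill subjects only, left-truncated
    interval (t1, t2] on the study time scale with event = death.
    """
    if transition not in _TRANSITIONS:
        raise ValueError(f"transition must be one of {_TRANSITIONS}")
    covs = list(data.covariates if covariates is None else covariates)
    cov_index = {c: i for i, c in enumerate(data.covariates)}
    ill = data.illness.astype(bool)
    if transition == 23:
        sub = ill
        time, entry = data.t2[sub], data.t1[sub]
        event = data.death[sub].astype(bool)
    else:
        sub = np.ones(data.n, bool)
        time, entry = data.t1, None
        if transition == 12:
            event = ill
        else:
            event = (~ill) & data.death.astype(bool)
    if not event.any():
        raise CoxError(f"no events for transition {transition}")
    W = data.W[sub]
    a = data.treatment[sub]
    cols = []
    if with_treatment:
        _check_both_arms(data.treatment)
        cols.append(a.astype(float))
    cols += [W[:, cov_index[c]] for c in covs]
    cols += [a * W[:, cov_index[c]] for c in interactions]
    X = np.column_stack(cols) if cols else None
    fit = fit_cox(time, event, X, entry)
    return BreslowHazard(fit=fit, covariates=covs, with_treatment=with_treatment,
                         interactions=list(interactions), cov_index=cov_index,
                         delayed_entry=transition == 23)


def fit_censoring(data: Dataset, covariates: Sequence[str] = (),
                  with_treatment: bool = False) -> CensoringModel:
    """Cox fits for the censoring hazards in state 1 and state 2.

    Default is the covariate-free working model (a Cox model with no
    covariate effects, i.e. Nelson–Aalen).  States with no censoring events
    yield a degenerate K ≡ 1 component with a warning.
    """
    covs = list(covariates)
    cov_index = {c: i for i, c in enumerate(data.covariates)}
    ill = data.illness.astype(bool)
    dead = data.death.astype(bool)

    def _one(sub, time, entry, event, delayed):
        if not event.any():
            warnings.warn("no censoring events; using K = 1", UserWarning)
            return None
        W = data.W[sub]
        a = data.treatment[sub]
        cols = []
        if with_treatment:
            cols.append(a.astype(float))
        cols += [W[:, cov_index[c]] for c in covs]
        X = np.column_stack(cols) if cols else None
        fit = fit_cox(time, event, X, entry)
        return BreslowHazard(fit=fit, covariates=covs, with_treatment=with_treatment,
                             cov_index=cov_index, delayed_entry=delayed)

    all_ = np.ones(data.n, bool)
    cens1 = (~ill) & (~dead)               # censored while in state 1
    state1 = _one(all_, data.t1, None, cens1, False)
    cens2 = ill & (~dead)                  # censored while in state 2
    state2 = _one(ill, data.t2[ill], data.t1[ill], cens2[ill], True)
    return CensoringModel(state1=state1, state2=state2)


def fit_nuisances(data: Dataset, *,
                  propensity_covs: Sequence[str] | None = None,
                  transition_covs: Sequence[str] | None = None,
                  censoring_covs: Sequence[str] = (),
                  clip: float = 0.01) -> NuisanceSet:
    """Fit all five components with the default main-effects working models
    (logistic propensity, main-effects Cox per transition, covariate-free
    censoring Cox)."""
    return NuisanceSet(
        lambda12=fit_transition_cox(data, 12, transition_covs),
        lambda13=fit_transition_cox(data, 13, transition_covs),
        lambda23=fit_transition_cox(data, 23, transition_covs),
        censoring=fit_censoring(data, censoring_covs),
        propensity=fit_propensity(data, propensity_covs, clip=clip),
        provenance="fitted",
    )


# ---------------------------------------------------------------------------
# closed-form oracle for the simulated generating processes
# ---------------------------------------------------------------------------

def true_nuisances(config) -> NuisanceSet:
    """Exact generating hazards of the simulation configs, in closed form.

    For study-2 configs this is only available at ``gamma_u = 0``: otherwise
    the generating hazards condition on the unmeasured risk factor and are
    not functions of the observables.
    """
    cw = config.coef_w
    if config.case is None:
        l12 = OracleHazard(config.b12, lambda a, W: cw * W[:, 0] + config.a12 * a
                           + config.gamma12 * a * W[:, 0])
        l13 = OracleHazard(config.b13, lambda a, W: cw * W[:, 0] + config.a13 * a
                           + config.gamma13 * (1 - a) * W[:, 0])
        l23 = OracleHazard(config.b23, lambda a, W: cw * W[:, 0] + config.a23 * a
                           + config.gamma23 * (1 - a) * W[:, 0], delayed_entry=True)
        cens_lp = lambda a, W: config.theta * W[:, 0]
        prop = OraclePropensity(lambda W: expit(-0.5 + W[:, 0] + config.zeta * W[:, 0] ** 2))
    else:
        if config.gamma_u != 0.0:
            raise ValueError(
                "oracle nuisances undefined for study 2 with gamma_u != 0 "
                "(hazards condition on the latent U)")
        b12a, b13a = config.study2_coefs()
        l12 = OracleHazard(config.b12, lambda a, W: cw * W[:, 0] + b12a * a)
        l13 = OracleHazard(config.b13, lambda a, W: cw * W[:, 0] + b13a * a)
        l23 = OracleHazard(config.b23, lambda a, W: cw * W[:, 0] + b13a * a,
                           delayed_entry=True)
        cens_lp = lambda a, W: np.zeros(W.shape[0])
        prop = OraclePropensity(lambda W: expit(-0.5 + W[:, 0]))
    cens = CensoringModel(
        state1=OracleHazard(config.b_c, cens_lp),
        state2=OracleHazard(config.b_c, cens_lp, delayed_entry=True),
    )
    return NuisanceSet(lambda12=l12, lambda13=l13, lambda23=l23,
                       censoring=cens, propensity=prop, provenance="oracle")
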