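"""Identifying functional, efficient influence function and estimators for
separable direct and indirect effects in the illness-death model.

Under the identification assumptions (consistency of the treatment
decomposition, conditional exchangeability, positivity and the dismissible
components conditions) the counterfactual terminal-event risk under
interventions ``(aD, aI)`` on the death-path and illness-path treatment
components is

    psi(tau, aD, aI) = E[ P13(tau, aD, aI, W) ],
    P13 = 1 − Omega_tau − ∫_0^tau S2(tau|r, aD, w) Omega_{r−} dLambda12(r|aI, w),
    Omega_r = exp{ −Lambda12(r|aI, w) − Lambda13(r|aD, w) },

a hybrid healthy-state survival that mixes the illness hazard under ``aI``
with the direct-death hazard under ``aD``.  Two estimators are provided:

* plug-in / G-computation: the empirical average of P13 at fitted nuisances;
* one-step: the sample mean of the efficient influence function, which adds
  inverse-probability-weighted martingale-residual corrections for the three
  transitions and is multiply robust (consistent when at most one transition
  hazard is misspecified, or when only the propensity and censoring models
  are misspecified).

All integrals against fitted step-function hazards are exact finite sums
over the baseline jump grids with predictable (left-limit) denominators;
closed-form (oracle) hazards are integrated by fixed-order Gauss–Legendre
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, EstimandResult
from .nuisance import NuisanceSet, PositivityError, hazard_ratio_12

_FLOOR = 1e-8
_GL_NODES = 64
_glx, _glw = np.polynomial.legendre.leggauss(_GL_NODES)

COMBOS = ((1, 1), (1, 0), (0, 1), (0, 0))
DEFAULT_TAU_GRID = (2.0, 5.0, 10.0, 15.0, 20.0, 25.0)


@dataclass
class EifTermBreakdown:
    """Per-subject decomposition of the efficient influence function:
    the three weighted martingale-integral terms and the G-computation
    term, summing to phi."""

    term_m12: np.ndarray
    term_m13: np.ndarray
    term_m23: np.ndarray
    term_gcomp: np.ndarray

    @property
    def phi(self) -> np.ndarray:
        return self.term_m12 + self.term_m13 + self.term_m23 + self.term_gcomp


# ---------------------------------------------------------------------------
# small numerics helpers
# ---------------------------------------------------------------------------

def _intexp(a, x):
    """∫_0^x exp(a u) du, stable as a -> 0."""
    a = np.asarray(a, float)
    x = np.asarray(x, float)
    ax = a * x
    small = np.abs(ax) < 1e-6
    safe = np.where(small, 1.0, a)
    series = x * (1.0 + ax / 2.0 + ax * ax / 6.0)
    with np.errstate(over="ignore"):
        exact = np.expm1(ax) / safe
    return np.where(small, series, exact)


def _gl_nodes(upper):
    """Gauss-Legendre nodes/weights on [0, upper] per row; upper (n,)."""
    upper = np.asarray(upper, float)
    s = 0.5 * upper[:, None] * (_glx[None, :] + 1.0)
    w = 0.5 * upper[:, None] * _glw[None, :]
    return s, w


def _check_floor(vals, what):
    m = np.min(vals) if np.size(vals) else 1.0
    if m < _FLOOR:
        idx = np.argwhere(np.asarray(vals) < _FLOOR)
        rows = np.unique(idx[:, 0])[:5]
        raise PositivityError(
            f"{what} below {_FLOOR:g} (positivity violation); "
            f"first offending subjects: {rows.tolist()}")


# ---------------------------------------------------------------------------
# oracle (closed-form constant-rate) backend
# ---------------------------------------------------------------------------

class _OracleCtx:
    """Per-dataset per-combo rate bundle for closed-form nuisances."""

    def __init__(self, nu: NuisanceSet, W, a_d, a_i):
        self.mu_i = nu.lambda12.rate(a_i, W)      # illness hazard, arm aI
        self.mu_d = nu.lambda12.rate(a_d, W)
        self.nu13_d = nu.lambda13.rate(a_d, W)
        self.nu13_i = nu.lambda13.rate(a_i, W)
        self.nu23_d = nu.lambda23.rate(a_d, W)
        s1 = nu.censoring.state1
        s2 = nu.censoring.state2
        n = self.mu_i.size
        self.c1_i = s1.rate(a_i, W) if s1 is not None else np.zeros(n)
        self.c1_d = s1.rate(a_d, W) if s1 is not None else np.zeros(n)
        self.c2_d = s2.rate(a_d, W) if s2 is not None else np.zeros(n)
        self.lam = self.mu_i + self.nu13_d        # Omega exponent rate
        self.k = self.nu23_d - self.lam

    def omega(self, s):
        return np.exp(-self.lam * s) if np.ndim(s) <= 1 else np.exp(-self.lam[:, None] * s)

    def _col(self, v, s):
        return v if np.ndim(s) <= 1 else v[:, None]

    def s2(self, tau, s):
        return np.exp(-self._col(self.nu23_d, s) * (tau - s))

    def J(self, s, tau):
        """∫_s^tau S2(tau|r) Omega_r dLambda12(r|aI)  (closed form)."""
        mu = self._col(self.mu_i, s)
        k = self._col(self.k, s)
        n23 = self._col(self.nu23_d, s)
        return mu * np.exp(-n23 * tau) * np.exp(k * s) * _intexp(k, tau - s)

    def h13(self, s, tau):
        return self._col(self.omega(tau), s) + self.J(s, tau)

    def h12(self, s, tau):
        return self.h13(s, tau) - self.s2(tau, s) * self.omega(s)

    def h23(self, s, tau):
        ratio = self._col(self.mu_i / self.mu_d, s)
        return ratio * self.omega(s) * self.s2(tau, s)


def _p13_oracle(nu, taus, a_d, a_i, W):
    ctx = _OracleCtx(nu, W, a_d, a_i)
    out = np.empty((ctx.mu_i.size, len(taus)))
    for j, tau in enumerate(taus):
        s, w = _gl_nodes(np.full(ctx.mu_i.size, tau))
        integrand = ctx.s2(tau, s) * ctx.omega(s) * ctx.mu_i[:, None]
        out[:, j] = 1.0 - ctx.omega(tau) - (integrand * w).sum(axis=1)
    return out


def _eif_oracle(nu, data: Dataset, taus, a_d, a_i):
    W = data.W
    t1, t2 = data.t1, data.t2
    eta = data.illness.astype(bool)
    dead = data.death.astype(bool)
    A = data.treatment
    ctx = _OracleCtx(nu, W, a_d, a_i)

    pi_i = nu.propensity.prob(a_i, W)
    pi_d = nu.propensity.prob(a_d, W)
    _check_floor(pi_i, "propensity pi(aI|w)")
    _check_floor(pi_d, "propensity pi(aD|w)")
    act_i = A == a_i           # only these subjects contribute IPW terms
    act_d = A == a_d
    w_i = act_i / pi_i
    w_d = act_d / pi_d

    g1_i_rate = ctx.mu_i + ctx.nu13_i + ctx.c1_i   # −log G1 slope, arm aI
    g1_d_rate = ctx.mu_d + ctx.nu13_d + ctx.c1_d
    g2_rate = ctx.nu23_d + ctx.c2_d

    p13 = _p13_oracle(nu, taus, a_d, a_i, W)
    n, m = len(t1), len(taus)
    tm12 = np.zeros((n, m))
    tm13 = np.zeros((n, m))
    tm23 = np.zeros((n, m))
    for j, tau in enumerate(taus):
        upper1 = np.minimum(t1, tau)
        s, wq = _gl_nodes(upper1)
        # G1 floors at the horizon, for contributing subjects only
        _check_floor(np.where(act_i, np.exp(-g1_i_rate * upper1), 1.0), "S1*K1 under aI")
        _check_floor(np.where(act_d, np.exp(-g1_d_rate * upper1), 1.0), "S1*K1 under aD")

        comp12 = np.where(act_i, (ctx.h12(s, tau) * ctx.mu_i[:, None]
                  * np.exp(np.where(act_i, g1_i_rate, 0.0)[:, None] * s) * wq).sum(axis=1), 0.0)
        jump12 = np.where(
            act_i & eta & (t1 <= tau),
            ctx.h12(t1, tau) * np.exp(np.where(act_i, g1_i_rate, 0.0) * t1), 0.0)
        tm12[:, j] = w_i * (jump12 - comp12)

        comp13 = np.where(act_d, (ctx.h13(s, tau) * ctx.nu13_d[:, None]
                  * np.exp(np.where(act_d, g1_d_rate, 0.0)[:, None] * s) * wq).sum(axis=1), 0.0)
        jump13 = np.where(
            act_d & (~eta) & dead & (t1 <= tau),
            ctx.h13(t1, tau) * np.exp(np.where(act_d, g1_d_rate, 0.0) * t1), 0.0)
        tm13[:, j] = w_d * (jump13 - comp13)

        # 2->3 part: prefactor at the illness time, bracket over (t1, tau]
        act23 = act_d & eta
        dur = np.maximum(np.minimum(t2, tau) - t1, 0.0)
        _check_floor(np.where(act23, np.exp(-g2_rate * dur), 1.0), "S2*K2")
        comp23 = ctx.nu23_d * _intexp(g2_rate, np.where(act23, dur, 0.0))
        jump23 = np.where(act23 & dead & (t2 <= tau),
                          np.exp(g2_rate * np.where(act23, dur, 0.0)), 0.0)
        pref = np.where(act23,
                        ctx.h23(t1, tau) * np.exp(np.where(act23, g1_d_rate, 0.0) * t1), 0.0)
        tm23[:, j] = w_d * eta * pref * (jump23 - comp23)
    return EifTermBreakdown(tm12, tm13, tm23, p13)


# ---------------------------------------------------------------------------
# step-function (Breslow) backend: exact sums over baseline jump grids
# ---------------------------------------------------------------------------

def _cum(haz):
    """(jump_times, increments, cumvals-with-leading-zero)."""
    return haz.jump_times, haz.base_increments, haz._cum


def _at(grid, cumvals, t, side):
    return cumvals[np.searchsorted(grid, t, side=side)]


class _StepCtx:
    def __init__(self, nu: NuisanceSet, data: Dataset, a_d, a_i):
        self.nu, self.data = nu, data
        W = data.W
        self.g12, self.d12, self.c12 = _cum(nu.lambda12)
        self.g13, self.d13, self.c13 = _cum(nu.lambda13)
        self.g23, self.d23, self.c23 = _cum(nu.lambda23)
        cs1, cs2 = nu.censoring.state1, nu.censoring.state2
        self.m12i = nu.lambda12.multiplier(a_i, W)
        self.m12d = nu.lambda12.multiplier(a_d, W)
        self.m13i = nu.lambda13.multiplier(a_i, W)
        self.m13d = nu.lambda13.multiplier(a_d, W)
        self.m23d = nu.lambda23.multiplier(a_d, W)
        n = len(data.df)
        if cs1 is not None:
            self.gc1, _, self.cc1 = _cum(cs1)
            self.mc1i = cs1.multiplier(a_i, W)
            self.mc1d = cs1.multiplier(a_d, W)
        else:
            self.gc1, self.cc1 = np.empty(0), np.zeros(1)
            self.mc1i = self.mc1d = np.zeros(n)
        if cs2 is not None:
            self.gc2, _, self.cc2 = _cum(cs2)
            self.mc2d = cs2.multiplier(a_d, W)
        else:
            self.gc2, self.cc2 = np.empty(0), np.zeros(1)
            self.mc2d = np.zeros(n)

        t1 = data.t1
        self.b12_t1L = _at(self.g12, self.c12, t1, "left")
        self.b12_t1R = _at(self.g12, self.c12, t1, "right")
        self.b13_t1L = _at(self.g13, self.c13, t1, "left")
        self.b13_t1R = _at(self.g13, self.c13, t1, "right")
        self.b23_t1R = _at(self.g23, self.c23, t1, "right")
        self.bc1_t1L = _at(self.gc1, self.cc1, t1, "left")
        self.bc2_t1R = _at(self.gc2, self.cc2, t1, "right")
        self.b23_t2L = _at(self.g23, self.c23, data.t2, "left")
        self.bc2_t2L = _at(self.gc2, self.cc2, data.t2, "left")
        # grid-aligned lookups
        self.b12L_g = self.c12[:-1]
        self.b12R_g = self.c12[1:]
        self.b13_g12_L = _at(self.g13, self.c13, self.g12, "left")
        self.b13_g12_R = _at(self.g13, self.c13, self.g12, "right")
        self.b23_g12_R = _at(self.g23, self.c23, self.g12, "right")
        self.bc1_g12_L = _at(self.gc1, self.cc1, self.g12, "left")
        self.b13L_g = self.c13[:-1]
        self.b12_g13_L = _at(self.g12, self.c12, self.g13, "left")
        self.bc1_g13_L = _at(self.gc1, self.cc1, self.g13, "left")
        self.b23L_g = self.c23[:-1]
        self.bc2_g23_L = _at(self.gc2, self.cc2, self.g23, "left")
        self.pos_g13_in_g12 = np.searchsorted(self.g12, self.g13, side="right")
        self.pos_t1_in_g12 = np.searchsorted(self.g12, t1, side="right")


def _p13_step_ctx(ctx: _StepCtx, taus):
    """P13 plus the tail-sum table used by the h-functions, per tau."""
    out_p13 = np.empty((ctx.m12i.size, len(taus)))
    tails, omtaus, b23taus = [], [], []
    for j, tau in enumerate(taus):
        b12_tau = _at(ctx.g12, ctx.c12, tau, "right")
        b13_tau = _at(ctx.g13, ctx.c13, tau, "right")
        b23_tau = _at(ctx.g23, ctx.c23, tau, "right")
        om_tau = np.exp(-ctx.m12i * b12_tau - ctx.m13d * b13_tau)
        mask = ctx.g12 <= tau
        om_left = np.exp(-np.outer(ctx.m12i, ctx.b12L_g)
                         - np.outer(ctx.m13d, ctx.b13_g12_L))
        s2 = np.exp(-np.outer(ctx.m23d, b23_tau - ctx.b23_g12_R))
        contrib = s2 * om_left * (ctx.m12i[:, None] * ctx.d12[None, :]) * mask
        # tail[:, k] = sum over jumps with index >= k; tail[:, K] = 0
        tail = np.concatenate(
            [np.cumsum(contrib[:, ::-1], axis=1)[:, ::-1], np.zeros((contrib.shape[0], 1))],
            axis=1)
        out_p13[:, j] = 1.0 - om_tau - tail[:, 0]
        tails.append(tail)
        omtaus.append(om_tau)
        b23taus.append(b23_tau)
    return out_p13, tails, omtaus, b23taus


def _eif_step(nu: NuisanceSet, data: Dataset, taus, a_d, a_i):
    ctx = _StepCtx(nu, data, a_d, a_i)
    W = data.W
    t1, t2 = data.t1, data.t2
    eta = data.illness.astype(bool)
    dead = data.death.astype(bool)
    A = data.treatment
    n = len(t1)

    pi_i = nu.propensity.prob(a_i, W)
    pi_d = nu.propensity.prob(a_d, W)
    _check_floor(pi_i, "propensity pi(aI|w)")
    _check_floor(pi_d, "propensity pi(aD|w)")
    act_i = A == a_i           # only these subjects contribute IPW terms
    act_d = A == a_d
    w_i = act_i / pi_i
    w_d = act_d / pi_d

    p13, tails, omtaus, b23taus = _p13_step_ctx(ctx, taus)

    # left-limit log-denominators (−log G1) at grid and subject times
    log_g1i_g12 = (np.outer(ctx.m12i, ctx.b12L_g) + np.outer(ctx.m13i, ctx.b13_g12_L)
                   + np.outer(ctx.mc1i, ctx.bc1_g12_L))
    log_g1d_g13 = (np.outer(ctx.m12d, ctx.b12_g13_L) + np.outer(ctx.m13d, ctx.b13L_g)
                   + np.outer(ctx.mc1d, ctx.bc1_g13_L))
    log_g1i_t1 = ctx.m12i * ctx.b12_t1L + ctx.m13i * ctx.b13_t1L + ctx.mc1i * ctx.bc1_t1L
    log_g1d_t1 = ctx.m12d * ctx.b12_t1L + ctx.m13d * ctx.b13_t1L + ctx.mc1d * ctx.bc1_t1L
    om_right_g12 = np.exp(-np.outer(ctx.m12i, ctx.b12R_g)
                          - np.outer(ctx.m13d, ctx.b13_g12_R))
    om_right_t1 = np.exp(-ctx.m12i * ctx.b12_t1R - ctx.m13d * ctx.b13_t1R)
    ratio12 = ctx.m12i / ctx.m12d

    tm12 = np.zeros((n, len(taus)))
    tm13 = np.zeros((n, len(taus)))
    tm23 = np.zeros((n, len(taus)))
    for j, tau in enumerate(taus):
        tail, om_tau, b23_tau = tails[j], omtaus[j], b23taus[j]
        upper1 = np.minimum(t1, tau)

        # --- 1->2 martingale term (weighted by arm aI) ------------------
        mask12 = (ctx.g12[None, :] <= upper1[:, None]) & act_i[:, None]
        h13_g12 = om_tau[:, None] + tail[:, 1:]
        s2_g12 = np.exp(-np.outer(ctx.m23d, b23_tau - ctx.b23_g12_R))
        h12_g12 = h13_g12 - np.where(ctx.g12[None, :] <= tau, s2_g12 * om_right_g12, 0.0)
        den12 = np.exp(-np.where(mask12, log_g1i_g12, 0.0))
        _check_floor(np.where(mask12, den12, 1.0), "G1 = S1*K1 under aI")
        comp12 = (h12_g12 * (ctx.m12i[:, None] * ctx.d12[None, :]) / den12 * mask12).sum(1)
        sel12 = act_i & eta & (t1 <= tau)
        h13_own = om_tau + tail[np.arange(n), ctx.pos_t1_in_g12]
        s2_own = np.exp(-ctx.m23d * (b23_tau - ctx.b23_t1R))
        h12_own = h13_own - s2_own * om_right_t1
        _check_floor(np.where(sel12, np.exp(-log_g1i_t1), 1.0), "G1(T1) under aI")
        jump12 = np.where(sel12, h12_own * np.exp(np.where(sel12, log_g1i_t1, 0.0)), 0.0)
        tm12[:, j] = w_i * (jump12 - comp12)

        # --- 1->3 martingale term (weighted by arm aD) ------------------
        mask13 = (ctx.g13[None, :] <= upper1[:, None]) & act_d[:, None]
        h13_g13 = om_tau[:, None] + tail[:, ctx.pos_g13_in_g12]
        den13 = np.exp(-np.where(mask13, log_g1d_g13, 0.0))
        _check_floor(np.where(mask13, den13, 1.0), "G1 = S1*K1 under aD")
        comp13 = (h13_g13 * (ctx.m13d[:, None] * ctx.d13[None, :]) / den13 * mask13).sum(1)
        sel13 = act_d & (~eta) & dead & (t1 <= tau)
        jump13 = np.where(sel13, h13_own * np.exp(np.where(sel13, log_g1d_t1, 0.0)), 0.0)
        tm13[:, j] = w_d * (jump13 - comp13)

        # --- 2->3 martingale term (ill subjects, arm aD) ----------------
        act23 = act_d & eta
        pref = np.where(act23, ratio12 * om_right_t1 * s2_own
                        * np.exp(np.where(act23, log_g1d_t1, 0.0)), 0.0)
        log_g2_t2 = (ctx.m23d * (ctx.b23_t2L - ctx.b23_t1R)
                     + ctx.mc2d * (ctx.bc2_t2L - ctx.bc2_t1R))
        sel23 = act23 & dead & (t2 <= tau)
        _check_floor(np.where(sel23, np.exp(-log_g2_t2), 1.0), "G2(T2)")
        jump23 = np.where(sel23, np.exp(np.where(sel23, log_g2_t2, 0.0)), 0.0)
        mask23 = (t1[:, None] < ctx.g23[None, :]) & (
            ctx.g23[None, :] <= np.minimum(t2, tau)[:, None]) & act23[:, None]
        log_g2_g = (ctx.m23d[:, None] * (ctx.b23L_g[None, :] - ctx.b23_t1R[:, None])
                    + ctx.mc2d[:, None] * (ctx.bc2_g23_L[None, :] - ctx.bc2_t1R[:, None]))
        den23 = np.exp(-np.where(mask23, log_g2_g, 0.0))
        _check_floor(np.where(mask23, den23, 1.0), "G2 = S2*K2")
        comp23 = ((ctx.m23d[:, None] * ctx.d23[None, :]) / den23 * mask23).sum(1)
        tm23[:, j] = w_d * eta * pref * (jump23 - comp23)
    return EifTermBreakdown(tm12, tm13, tm23, p13)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def omega(nu: NuisanceSet, r, a_d, a_i, w, *, left: bool = False) -> np.ndarray:
    """Hybrid healthy-state survival Omega_r(aD, aI, w) (or its left limit)."""
    W = np.atleast_2d(np.asarray(w, float))
    l12 = nu.lambda12.cumhaz(r, a_i, W, left=left)
    l13 = nu.lambda13.cumhaz(r, a_d, W, left=left)
    return np.exp(-(l12 + l13))


def p13(nu: NuisanceSet, tau, a_d, a_i, w) -> np.ndarray:
    """Counterfactual terminal-event risk P13(tau, aD, aI, w), vectorised
    over rows of ``w``.  ``tau`` may be scalar or a grid (returns (n, m))."""
    W = np.atleast_2d(np.asarray(w, float))
    taus = np.atleast_1d(np.asarray(tau, float))
    if nu.is_oracle:
        out = _p13_oracle(nu, taus, a_d, a_i, W)
    else:
        # minimal step context: only the fields _p13_step_ctx consumes
        ctx = _StepCtx.__new__(_StepCtx)
        ctx.g12, ctx.d12, ctx.c12 = _cum(nu.lambda12)
        ctx.g13, _, ctx.c13 = _cum(nu.lambda13)
        ctx.g23, _, ctx.c23 = _cum(nu.lambda23)
        ctx.m12i = nu.lambda12.multiplier(a_i, W)
        ctx.m13d = nu.lambda13.multiplier(a_d, W)
        ctx.m23d = nu.lambda23.multiplier(a_d, W)
        ctx.b12L_g = ctx.c12[:-1]
        ctx.b13_g12_L = _at(ctx.g13, ctx.c13, ctx.g12, "left")
        ctx.b23_g12_R = _at(ctx.g23, ctx.c23, ctx.g12, "right")
        out, _, _, _ = _p13_step_ctx(ctx, taus)
    if np.ndim(tau) == 0:
        return out[:, 0]
    return out


def h_weights(nu: NuisanceSet, s, tau, a_d, a_i, w):
    """EIF weight functions (h12, h13, h23) at time ``s`` for horizon tau.

    h13(s) = Omega_tau + ∫_(s,tau] S2(tau|r) Omega_{r−} dLambda12(r|aI);
    h12 subtracts S2(tau|s) Omega_s; h23 multiplies the illness-hazard
    ratio between arms by Omega_s S2(tau|s).
    """
    W = np.atleast_2d(np.asarray(w, float))
    if nu.is_oracle:
        ctx = _OracleCtx(nu, W, a_d, a_i)
        return ctx.h12(s, tau), ctx.h13(s, tau), ctx.h23(s, tau)
    g12, d12, c12 = _cum(nu.lambda12)
    m12i = nu.lambda12.multiplier(a_i, W)
    m13d = nu.lambda13.multiplier(a_d, W)
    m23d = nu.lambda23.multiplier(a_d, W)
    g13, _, c13 = _cum(nu.lambda13)
    g23, _, c23 = _cum(nu.lambda23)
    om_tau = np.exp(-m12i * _at(g12, c12, tau, "right")
                    - m13d * _at(g13, c13, tau, "right"))
    b23_tau = _at(g23, c23, tau, "right")
    sel = (g12 > s) & (g12 <= tau)
    r = g12[sel]
    om_left = np.exp(-np.outer(m12i, c12[:-1][sel])
                     - np.outer(m13d, _at(g13, c13, r, "left")))
    s2_r = np.exp(-np.outer(m23d, b23_tau - _at(g23, c23, r, "right")))
    h13 = om_tau + (s2_r * om_left * (m12i[:, None] * d12[sel][None, :])).sum(1)
    om_s = omega(nu, s, a_d, a_i, W)
    s2_s = np.exp(-m23d * (b23_tau - _at(g23, c23, s, "right")))
    h12 = h13 - np.where(s <= tau, s2_s * om_s, 0.0)
    h23 = hazard_ratio_12(nu.lambda12, s, a_i, a_d, W) * om_s * s2_s
    return h12, h13, h23


def _full_data(nu: NuisanceSet) -> NuisanceSet:
    from .nuisance import CensoringModel
    return NuisanceSet(nu.lambda12, nu.lambda13, nu.lambda23,
                       CensoringModel(None, None), nu.propensity, nu.provenance)


def eif_terms(nu: NuisanceSet, data: Dataset, tau, a_d, a_i,
              *, full_data: bool = False) -> EifTermBreakdown:
    """Per-subject EIF term breakdown; ``tau`` scalar or grid (arrays get a
    trailing tau axis).  ``full_data=True`` evaluates the uncensored-data
    influence function (all censoring survival factors set to one)."""
    if full_data:
        nu = _full_data(nu)
    taus = np.atleast_1d(np.asarray(tau, float))
    fn = _eif_oracle if nu.is_oracle else _eif_step
    br = fn(nu, data, taus, a_d, a_i)
    if np.ndim(tau) == 0:
        return EifTermBreakdown(br.term_m12[:, 0], br.term_m13[:, 0],
                                br.term_m23[:, 0], br.term_gcomp[:, 0])
    return br


def eif_phi(nu: NuisanceSet, data: Dataset, tau, a_d, a_i,
            *, full_data: bool = False) -> np.ndarray:
    """Per-subject EIF estimating-function values phi_i."""
    return eif_terms(nu, data, tau, a_d, a_i, full_data=full_data).phi


def plug_in(nu: NuisanceSet, data: Dataset, tau, a_d, a_i):
    """G-computation estimator: empirical mean of P13 over the covariates."""
    vals = p13(nu, tau, a_d, a_i, data.W)
    return vals.mean(axis=0) if np.ndim(tau) else float(vals.mean())

def one_step(nu: NuisanceSet, data: Dataset, tau, a_d, a_i):
    """One-step (EIF estimating-equation) estimator: mean of phi_i.

    Equals the plug-in plus the mean of the martingale correction terms.
    """
    phi = eif_phi(nu, data, tau, a_d, a_i)
    return phi.mean(axis=0) if np.ndim(tau) else float(phi.mean())


def contrasts(nu: NuisanceSet, data: Dataset, tau_grid=DEFAULT_TAU_GRID,
              estimator: str = "one_step") -> EstimandResult:
    """All four counterfactual risks and the SDE/SIE/TE contrasts on a grid."""
    if estimator not in {"plug_in", "one_step"}:
        raise ValueError("estimator must be 'plug_in' or 'one_step'")
    taus = np.asarray(tau_grid, float)
    est = plug_in if estimator == "plug_in" else one_step
    psi = {}
    for ad, ai in COMBOS:
        vals = est(nu, data, taus, ad, ai)
        for t, v in zip(taus, np.atleast_1d(vals)):
            psi[(float(t), ad, ai)] = float(v)
    sde = {(t, ai): psi[(t, 1, ai)] - psi[(t, 0, ai)]
           for t in taus for ai in (0, 1)}
    sie = {(t, ad): psi[(t, ad, 1)] - psi[(t, ad, 0)]
           for t in taus for ad in (0, 1)}
    te = {float(t): psi[(t, 1, 1)] - psi[(t, 0, 0)] for t in taus}
    return EstimandResult(tau_grid=taus, psi=psi, sde=sde, sie=sie, te=te,
                          estimator=estimator)
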