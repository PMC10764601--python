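"""Cox proportional-hazards fitting with Breslow tie handling, left
truncation (delayed entry) and the Breslow step-function baseline.

The estimating machinery downstream integrates against the fitted baseline
jump measure exactly (finite sums over the event grid with predictable left
limits), which requires direct access to the jump times and increments of
the baseline cumulative hazard — hence this purpose-built fitter.  With no
covariates the Breslow baseline reduces exactly to the Nelson–Aalen
estimator.

The risk set at an event time ``u`` is ``{j : entry_j < u <= exit_j}``.
Partial likelihood (Breslow ties):

    l(beta) = sum_k [ s_k' beta − D_k log R_k(beta) ],

with ``s_k`` the covariate sum of the ``D_k`` events at the k-th distinct
event time and ``R_k`` the risk-set sum of ``exp(x' beta)``.  Baseline
increments are ``dLambda0_k = D_k / R_k(beta_hat)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CoxError(RuntimeError):
    """Non-convergence or degenerate risk structure in a Cox fit."""


@dataclass
class CoxFit:
    beta: np.ndarray            # (p,)
    se: np.ndarray              # (p,) from the inverse information
    jump_times: np.ndarray      # distinct event times, ascending
    base_increments: np.ndarray  # Breslow baseline jumps dLambda0
    loglik: float
    n_events: int


def _suffix_sums(keys_sorted, order, values, queries):
    """For each query u: sum of values[j] over keys[j] >= u (keys pre-sorted
    ascending via ``order``)."""
    v = values[order]
    cs = np.cumsum(v[::-1], axis=0)[::-1]
    pad = np.zeros((1,) + v.shape[1:])
    cs = np.concatenate([cs, pad], axis=0)
    idx = np.searchsorted(keys_sorted, queries, side="left")
    return cs[idx]


def _risk_quantities(entry, exit_, u, w, xw=None, xxw=None):
    """Risk-set sums at each distinct event time u.

    Exploits entry <= exit: {entry < u <= exit} sums equal
    (suffix over exit >= u) minus (suffix over entry >= u).
    """
    o_exit = np.argsort(exit_, kind="stable")
    o_entry = np.argsort(entry, kind="stable")
    exit_sorted = exit_[o_exit]
    entry_sorted = entry[o_entry]

    def _sum(vals):
        return (_suffix_sums(exit_sorted, o_exit, vals, u)
                - _suffix_sums(entry_sorted, o_entry, vals, u))

    out = [_sum(w)]
    if xw is not None:
        out.append(_sum(xw))
    if xxw is not None:
        out.append(_sum(xxw))
    return out


def fit_cox(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray | None = None,
    entry: np.ndarray | None = None,
    *,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox model; ``X`` may be None/empty for a covariate-free
    (Nelson–Aalen) baseline.  ``entry`` enables delayed entry."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    n = time.size
    entry = np.zeros(n) if entry is None else np.asarray(entry, float)
    if np.any(entry >= time):
        raise CoxError("entry time must precede exit time for every subject")
    if X is None:
        X = np.empty((n, 0))
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]

    if not event.any():
        raise CoxError("no events for this transition")

    u, inv = np.unique(time[event], return_inverse=True)
    d_k = np.bincount(inv).astype(float)          # multiplicity per event time
    if p:
        s_k = np.zeros((u.size, p))
        np.add.at(s_k, inv, X[event])
    xx = None
    if p:
        iu, ju = np.triu_indices(p)
        xx = X[:, iu] * X[:, ju]                   # packed upper triangle

    beta = np.zeros(p)
    loglik = -np.inf
    for _ in range(max_iter):
        if p == 0:
            w = np.ones(n)
            (r0,) = _risk_quantities(entry, time, u, w)
            loglik = float(-(d_k * np.log(r0)).sum())
            break
        lp = X @ beta
        lp -= lp.max()                             # guard overflow; cancels in ratios
        w = np.exp(lp)
        r0, r1, r2 = _risk_quantities(entry, time, u, w, X * w[:, None], xx * w[:, None])
        if np.any(r0 <= 0):
            raise CoxError("empty risk set at an event time")
        new_loglik = float((s_k * beta).sum() - (d_k * np.log(r0)).sum()
                           + (d_k.sum()) * 0.0)
        xbar = r1 / r0[:, None]
        grad = (s_k - d_k[:, None] * xbar).sum(axis=0)
        # information matrix from packed second moments
        info = np.zeros((p, p))
        m2 = (d_k[:, None] * (r2 / r0[:, None])).sum(axis=0)
        info[iu, ju] = m2
        info[ju, iu] = m2
        info -= np.einsum("k,ki,kj->ij", d_k, xbar, xbar)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxError("singular information matrix") from exc
        # step-halving on the (concave) partial likelihood
        scale = 1.0
        while True:
            cand = beta + scale * step
            if np.all(np.isfinite(cand)) and np.abs(cand).max() < 50:
                break
            scale /= 2.0
            if scale < 1e-8:
                raise CoxError("divergent coefficients (separation?)")
        beta = cand
        if np.abs(grad).max() < tol or np.abs(scale * step).max() < tol:
            loglik = new_loglik
            break
    else:
        raise CoxError("Newton-Raphson failed to converge")

    # Breslow baseline and coefficient SEs at the solution
    if p:
        lp = X @ beta
        w = np.exp(lp - 0.0)
        r0, r1, r2 = _risk_quantities(entry, time, u, w, X * w[:, None], xx * w[:, None])
        xbar = r1 / r0[:, None]
        info = np.zeros((p, p))
        m2 = (d_k[:, None] * (r2 / r0[:, None])).sum(axis=0)
        info[iu, ju] = m2
        info[ju, iu] = m2
        info -= np.einsum("k,ki,kj->ij", d_k, xbar, xbar)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        loglik = float((s_k * beta).sum() - (d_k * np.log(r0)).sum())
    else:
        w = np.ones(n)
        (r0,) = _risk_quantities(entry, time, u, w)
        se = np.empty(0)
    if not np.all(np.isfinite(beta)):
        raise CoxError("non-finite coefficients")
    increments = d_k / r0
    return CoxFit(
        beta=beta, se=se, jump_times=u, base_increments=increments,
        loglik=loglik, n_events=int(d_k.sum()),
    )
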