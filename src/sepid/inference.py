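"""Bootstrap inference and the simulation-study harness.

Variance estimation follows the nonparametric bootstrap: subjects are
resampled with replacement, every nuisance model is refitted on each
replicate, and Wald confidence intervals use the bootstrap standard
deviation (an explicit sandwich variance for the one-step estimator is not
implemented; its stacked-estimating-equation form is unwieldy once the
baseline hazards are nonparametric).

The harness replays the two simulation studies: for each scenario it draws
datasets, fits the default working models (main-effects logistic propensity,
main-effects Cox transition hazards, covariate-free censoring Cox), computes
the plug-in and one-step separable-direct-effect curves, optionally
bootstraps, and aggregates bias, empirical SE, Wald coverage and the
mean-estimated-SE/empirical-SE ratio against a Monte-Carlo truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import Dataset, EstimandResult
from .estimands import DEFAULT_TAU_GRID, contrasts, eif_terms
from .nuisance import NuisanceSet, fit_nuisances
from .simulate import (SimulationConfig, derived_seeds, make_scenario,
                       simulate_observed_study1, simulate_observed_study2,
                       true_sde_mc)

logger = logging.getLogger("sepid")


def _sde_both(data: Dataset, taus, a_i: int, nu: NuisanceSet | None = None,
              **fit_kw):
    """(plug-in SDE curve, one-step SDE curve) at tau grid, for one dataset."""
    if nu is None:
        nu = fit_nuisances(data, **fit_kw)
    taus = np.asarray(taus, float)
    est = {}
    for ad in (0, 1):
        br = eif_terms(nu, data, taus, ad, a_i)
        est[ad] = (br.term_gcomp.mean(axis=0), br.phi.mean(axis=0))
    return est[1][0] - est[0][0], est[1][1] - est[0][1]


def bootstrap_ci(data: Dataset, *, tau_grid=DEFAULT_TAU_GRID,
                 estimator: str = "one_step", n_boot: int = 250,
                 seed: int = 0, level: float = 0.95,
                 percentile: bool = False, max_fail_frac: float = 0.10,
                 **fit_kw) -> EstimandResult:
    """Point estimates with bootstrap SEs and confidence intervals.

    Nuisances are refitted on every resample.  Replicate-level fit failures
    are logged and skipped; more than ``max_fail_frac`` failures aborts.
    Wald intervals (estimate ± z·SE) are the default; percentile intervals
    are available behind the flag.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    nu = fit_nuisances(data, **fit_kw)
    res = contrasts(nu, data, tau_grid, estimator)
    rng = np.random.default_rng(seed)
    reps: list[pd.DataFrame] = []
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, data.n, size=data.n)
        try:
            bnu = fit_nuisances(data.subset(idx), **fit_kw)
            bres = contrasts(bnu, data.subset(idx), tau_grid, estimator)
        except Exception as exc:  # noqa: BLE001 - replicate-level guard
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            if failures > max_fail_frac * n_boot:
                raise RuntimeError(
                    f"more than {max_fail_frac:.0%} of bootstrap replicates failed")
            continue
        reps.append(_flatten(bres))
    stacked = pd.concat(reps, axis=1)
    se = stacked.std(axis=1, ddof=1)
    z = norm.ppf(0.5 + level / 2.0)
    point = _flatten(res)
    res.se = {k: float(se.iloc[i]) for i, k in enumerate(point.index)}
    if percentile:
        lo = stacked.quantile(0.5 - level / 2.0, axis=1)
        hi = stacked.quantile(0.5 + level / 2.0, axis=1)
        res.ci = {k: (float(lo.iloc[i]), float(hi.iloc[i]))
                  for i, k in enumerate(point.index)}
    else:
        res.ci = {k: (float(point.iloc[i] - z * se.iloc[i]),
                      float(point.iloc[i] + z * se.iloc[i]))
                  for i, k in enumerate(point.index)}
    return res


def _flatten(res: EstimandResult) -> pd.Series:
    vals, keys = [], []
    for (tau, ad, ai), v in sorted(res.psi.items()):
        keys.append(("psi", tau, ad, ai)); vals.append(v)
    for (tau, ai), v in sorted(res.sde.items()):
        keys.append(("sde", tau, ai)); vals.append(v)
    for (tau, ad), v in sorted(res.sie.items()):
        keys.append(("sie", tau, ad)); vals.append(v)
    for tau, v in sorted(res.te.items()):
        keys.append(("te", tau)); vals.append(v)
    return pd.Series(vals, index=keys)


@dataclass
class SimStudySummary:
    """Aggregated performance metrics, one row per
    (scenario, estimator, tau): bias, empirical SE, Wald coverage,
    mean estimated SE / empirical SE, the MC truth and its SE."""

    table: pd.DataFrame
    n_datasets: int
    n_failed: int = 0
    per_dataset: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_simulation_study(study: int = 1, scenarios=("i",), *,
                         n_datasets: int = 200, n: int = 400,
                         tau_grid=DEFAULT_TAU_GRID, n_boot: int = 0,
                         master_seed: int = 0, a_i: int = 1,
                         gamma_u_grid=(0.0,), n_mc_truth: int = 200_000,
                         level: float = 0.95,
                         keep_per_dataset: bool = False) -> SimStudySummary:
    """Replay a simulation study and aggregate estimator performance.

    ``scenarios`` are study-1 ids ("i".."viii") or study-2 cases
    ("I".."IV", crossed with ``gamma_u_grid``).  The target is the
    separable direct effect SDE(tau, a_i) on ``tau_grid``.  Coverage and
    SE accuracy are only reported when ``n_boot > 0``.
    """
    taus = np.asarray(tau_grid, float)
    z = norm.ppf(0.5 + level / 2.0)
    cells = []
    if study == 1:
        cells = [(sid, make_scenario(1, sid, n=n)) for sid in scenarios]
        simulate = simulate_observed_study1
    elif study == 2:
        for sid in scenarios:
            for gu in gamma_u_grid:
                cells.append((f"{sid}:gammaU={gu:g}",
                              make_scenario(2, sid, gamma_u=gu, n=n)))
        simulate = simulate_observed_study2
    else:
        raise ValueError("study must be 1 or 2")

    rows, per_rows = [], []
    n_failed_total = 0
    for label, config in cells:
        truth, truth_se = true_sde_mc(config, a_i, taus, n_mc=n_mc_truth,
                                      seed=master_seed + 10_000)
        seeds = derived_seeds(master_seed, n_datasets + 1)
        est = {"plug_in": [], "one_step": []}
        ses = {"plug_in": [], "one_step": []}
        n_failed = 0
        for k in range(n_datasets):
            cfg_k = SimulationConfig(**{**config.__dict__, "seed": seeds[k]})
            data = simulate(cfg_k)
            try:
                sde_pi, sde_os = _sde_both(data, taus, a_i)
            except Exception as exc:  # noqa: BLE001
                n_failed += 1
                logger.warning("dataset %d (%s) failed: %s", k, label, exc)
                continue
            est["plug_in"].append(sde_pi)
            est["one_step"].append(sde_os)
            if n_boot > 0:
                rng = np.random.default_rng(seeds[k] + 1)
                reps = {"plug_in": [], "one_step": []}
                fails = 0
                for _ in range(n_boot):
                    idx = rng.integers(0, data.n, size=data.n)
                    try:
                        bp, bo = _sde_both(data.subset(idx), taus, a_i)
                    except Exception:  # noqa: BLE001
                        fails += 1
                        if fails > 0.1 * n_boot:
                            raise
                        continue
                    reps["plug_in"].append(bp)
                    reps["one_step"].append(bo)
                for name in ("plug_in", "one_step"):
                    ses[name].append(np.std(np.asarray(reps[name]), axis=0, ddof=1))
            if keep_per_dataset:
                for j, t in enumerate(taus):
                    per_rows.append((label, k, t, sde_pi[j], sde_os[j]))
        n_failed_total += n_failed
        for name in ("plug_in", "one_step"):
            e = np.asarray(est[name])          # (reps, taus)
            bias = e.mean(axis=0) - truth
            emp_se = e.std(axis=0, ddof=1)
            if n_boot > 0:
                s = np.asarray(ses[name])
                cover = ((np.abs(e - truth) <= z * s).mean(axis=0))
                se_ratio = s.mean(axis=0) / emp_se
            else:
                cover = np.full(taus.shape, np.nan)
                se_ratio = np.full(taus.shape, np.nan)
            for j, t in enumerate(taus):
                rows.append({
                    "scenario": label, "estimator": name, "tau": t,
                    "bias": bias[j], "empirical_se": emp_se[j],
                    "coverage": cover[j], "se_ratio": se_ratio[j],
                    "truth": truth[j], "truth_mcse": truth_se[j],
                    "n_datasets": e.shape[0],
                })
    table = pd.DataFrame(rows)
    per = pd.DataFrame(per_rows, columns=["scenario", "dataset", "tau",
                                          "plug_in", "one_step"]) if keep_per_dataset else None
    return SimStudySummary(table=table, n_datasets=n_datasets,
                           n_failed=n_failed_total, per_dataset=per)
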