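"""Cox/Breslow fitter: identities, recovery and an independent library
cross-check (tie-free data makes Efron and Breslow tie handling coincide)."""

import numpy as np
import pytest

import sepid as sp
from sepid.cox import CoxError, fit_cox


def test_covariate_free_breslow_equals_nelson_aalen(study1_data):
    """With no covariates the Breslow baseline is the Nelson-Aalen estimator."""
    t1 = study1_data.t1
    ev = study1_data.illness.astype(bool)
    fit = fit_cox(t1, ev)
    # manual Nelson-Aalen: d_k / (number at risk)
    order = np.argsort(t1)
    at_risk = np.array([(t1 >= u).sum() for u in fit.jump_times])
    np.testing.assert_allclose(fit.base_increments, 1.0 / at_risk, rtol=0, atol=1e-14)


def test_matches_lifelines_without_ties(study1_data):
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd
    df = pd.DataFrame({
        "t": study1_data.t1,
        "e": study1_data.illness,
        "a": study1_data.treatment,
        "w": study1_data.W[:, 0],
    })
    cph = lifelines.CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    fit = fit_cox(df["t"].values, df["e"].values.astype(bool),
                  df[["a", "w"]].values)
    np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)
    np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-4)
    # Breslow cumulative baseline (lifelines centres at the covariate means)
    bch = cph.baseline_cumulative_hazard_
    shift = float(np.exp(df[["a", "w"]].mean().values @ fit.beta))
    for t in (5.0, 15.0, 30.0):
        mine = fit.base_increments[fit.jump_times <= t].sum() * shift
        pos = np.searchsorted(bch.index.values, t, side="right") - 1
        theirs = bch.iloc[pos, 0]
        assert abs(mine - theirs) / theirs < 1e-3


def test_delayed_entry_matches_lifelines(study1_data):
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd
    ill = study1_data.illness.astype(bool)
    df = pd.DataFrame({
        "entry": study1_data.t1[ill], "t": study1_data.t2[ill],
        "e": study1_data.death[ill], "a": study1_data.treatment[ill],
        "w": study1_data.W[ill, 0],
    })
    cph = lifelines.CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e", entry_col="entry")
    fit = fit_cox(df["t"].values, df["e"].values.astype(bool),
                  df[["a", "w"]].values, entry=df["entry"].values)
    np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)


def test_risk_set_with_delayed_entry_brute_force():
    """Breslow increments equal d/sum(exp(lp)) over {entry < u <= exit}."""
    rng = np.random.default_rng(6)
    n = 40
    entry = rng.random(n) * 2
    exit_ = entry + 0.1 + rng.exponential(2, n)
    event = rng.random(n) < 0.7
    x = rng.normal(size=(n, 1))
    fit = fit_cox(exit_, event, x, entry)
    lp = np.exp(x[:, 0] * fit.beta[0])
    for u, inc in zip(fit.jump_times, fit.base_increments):
        risk = (entry < u) & (u <= exit_)
        d = ((exit_ == u) & event).sum()
        assert abs(inc - d / lp[risk].sum()) < 1e-12


@pytest.mark.parametrize("transition,true_beta", [
    (12, (1.0, np.log(2))),
    (13, (0.5, np.log(2))),
    (23, (0.5, np.log(2))),
])
def test_transition_coefficient_recovery(big_study1_data, transition, true_beta):
    _, data = big_study1_data
    model = sp.fit_transition_cox(data, transition)
    for b, truth, se in zip(model.fit.beta, true_beta, model.fit.se):
        assert abs(b - truth) < 3 * se


def test_censoring_recovery_covariate_free(big_study1_data):
    cfg, data = big_study1_data
    cens = sp.fit_censoring(data)
    # K1(t) should track exp(-0.035 t) on [0, 25]
    for t in (5.0, 15.0, 25.0):
        k1 = cens.K1(t, 0, np.zeros((1, 1)))[0]
        assert abs(k1 - np.exp(-cfg.b_c * t)) < 0.03


def test_propensity_recovery(big_study1_data):
    _, data = big_study1_data
    prop = sp.fit_propensity(data)
    assert abs(prop.beta[0] - (-0.5)) < 3 * prop.se[0]
    assert abs(prop.beta[1] - 1.0) < 3 * prop.se[1]


def test_propensity_intercept_only_when_treatment_independent():
    rng = np.random.default_rng(2)
    import pandas as pd
    n = 4000
    df = pd.DataFrame({
        "time1": rng.exponential(5, n), "time2": 0.0, "illness": 0,
        "death": 1, "treatment": (rng.random(n) < 0.3).astype(int),
        "w": rng.random(n),
    })
    df["time2"] = df["time1"]
    data = sp.validate_dataset(sp.Dataset(df, ["w"]))
    prop = sp.fit_propensity(data, covariates=[])
    from scipy.special import expit
    assert abs(expit(prop.beta[0]) - df["treatment"].mean()) < 1e-6


def test_single_arm_raises_positivity():
    import pandas as pd
    df = pd.DataFrame({"time1": [1.0, 2.0], "time2": [1.0, 2.0],
                       "illness": [0, 0], "death": [1, 1],
                       "treatment": [1, 1], "w": [0.1, 0.2]})
    data = sp.Dataset(df, ["w"])
    with pytest.raises(sp.PositivityError):
        sp.fit_propensity(data)


def test_no_23_events_raises(study1_data):
    import pandas as pd
    df = study1_data.df.copy()
    df["illness"] = 0
    df["time2"] = df["time1"]
    data = sp.Dataset(df, ["w"])
    with pytest.raises(CoxError, match="no events"):
        sp.fit_transition_cox(data, 23)


def test_no_censoring_gives_unit_K(study1_data):
    import pandas as pd
    df = study1_data.df.copy()
    df["death"] = 1  # everyone observed to die
    data = sp.Dataset(df, ["w"])
    with pytest.warns(UserWarning, match="no censoring"):
        cens = sp.fit_censoring(data)
    assert cens.state1 is None and cens.state2 is None
    assert np.all(cens.K1(10.0, 1, np.zeros((3, 1))) == 1.0)


def test_cumhaz_monotone_and_zero_at_origin(fitted_nuisances):
    h = fitted_nuisances.lambda12
    w = np.array([[0.4]])
    ts = np.linspace(0.0, 30.0, 50)
    vals = np.array([h.cumhaz(t, 1, w)[0] for t in ts])
    assert vals[0] == 0.0
    assert np.all(np.diff(vals) >= 0)


def test_extrapolation_warns(fitted_nuisances):
    h = fitted_nuisances.lambda12
    last = h.jump_times[-1]
    with pytest.warns(sp.nuisance.ExtrapolationWarning):
        h.cumhaz(last * 2, 1, np.array([[0.5]]))


def test_oracle_hazard_closed_form(study1_config):
    nu = sp.true_nuisances(study1_config)
    w = np.array([[0.0]])
    # 1->3 hazard at a=1, w=0 is 0.026 e^{0.5} t
    val = nu.lambda13.cumhaz(10.0, 1, w)[0]
    assert abs(val - 0.026 * np.exp(0.5) * 10.0) < 1e-12
    k1 = nu.censoring.K1(10.0, 0, w)[0]
    assert abs(k1 - np.exp(-0.035 * 10.0)) < 1e-12


def test_hazard_ratio_12(fitted_nuisances, study1_config):
    w = np.array([[0.5]])
    r = sp.hazard_ratio_12(fitted_nuisances.lambda12, 3.0, 1, 1, w)
    assert abs(r[0] - 1.0) < 1e-12
    oracle = sp.true_nuisances(study1_config)
    r = sp.hazard_ratio_12(oracle.lambda12, 3.0, 1, 0, w)
    assert abs(r[0] - np.exp(1.0)) < 1e-12  # gamma12=0: ratio = exp(aI - aD)
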