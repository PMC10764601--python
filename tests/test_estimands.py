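"""Identifying functional and EIF: closed-form oracles, boundary
identities, estimating-function unbiasedness and robustness structure."""

import numpy as np
import pytest
from scipy.integrate import quad

import sepid as sp
from sepid.estimands import eif_terms
from sepid.nuisance import (CensoringModel, NuisanceSet, OracleHazard,
                            OraclePropensity)


def closed_form_p13(l12, l13, l23, tau):
    """Analytic integral of the identifying functional for constant rates.

    1 - e^{-L tau} - l12 e^{-l23 tau}(1 - e^{-(L - l23) tau})/(L - l23),
    L = l12 + l13.  Verified below against brute-force quadrature before it
    is used as an oracle elsewhere.
    """
    L = l12 + l13
    return (1.0 - np.exp(-L * tau)
            - l12 * np.exp(-l23 * tau) * (1 - np.exp(-(L - l23) * tau)) / (L - l23))


def test_closed_form_agrees_with_brute_force_quadrature():
    l12, l13, l23, tau = 0.11, 0.045, 0.09, 17.0
    integral, _ = quad(lambda r: np.exp(-l23 * (tau - r)) * np.exp(-(l12 + l13) * r) * l12,
                       0.0, tau, epsabs=1e-12)
    brute = 1.0 - np.exp(-(l12 + l13) * tau) - integral
    assert abs(closed_form_p13(l12, l13, l23, tau) - brute) < 1e-10


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.floats(-5.0, 5.0), st.floats(0.0, 30.0))
def test_stable_exponential_integral_matches_quadrature(a, x):
    from sepid.estimands import _intexp
    want, _ = quad(lambda u: np.exp(a * u), 0.0, x)
    assert abs(float(_intexp(a, x)) - want) < 1e-6 * max(1.0, abs(want))


def _flat_oracle(l12=0.1, l13=0.2, l23=0.15, c=0.0, pi1=0.5):
    """Covariate-free constant-rate nuisance set (treatment-free hazards)."""
    zero = lambda a, W: np.zeros(W.shape[0])
    return NuisanceSet(
        lambda12=OracleHazard(l12, zero),
        lambda13=OracleHazard(l13, zero),
        lambda23=OracleHazard(l23, zero, delayed_entry=True),
        censoring=CensoringModel(
            OracleHazard(c, zero) if c else None,
            OracleHazard(c, zero, delayed_entry=True) if c else None),
        propensity=OraclePropensity(lambda W: np.full(W.shape[0], pi1)),
        provenance="oracle",
    )


def test_omega_trivials():
    nu = _flat_oracle()
    w = np.zeros((1, 1))
    assert sp.omega(nu, 0.0, 1, 1, w)[0] == 1.0
    # aD = aI collapses to the state-1 survival
    assert abs(sp.omega(nu, 2.0, 1, 1, w)[0] - np.exp(-0.3 * 2)) < 1e-12
    # mixed arms with rates 0.1 (aI) and 0.2 (aD): exp(-0.3) at r=1
    assert abs(sp.omega(nu, 1.0, 0, 1, w)[0] - np.exp(-0.3)) < 1e-12


def test_p13_boundaries_and_no_illness_path():
    nu = _flat_oracle()
    w = np.zeros((1, 1))
    assert sp.p13(nu, 0.0, 1, 1, w)[0] == 0.0
    # Lambda12 == 0: risk reduces to 1 - exp(-Lambda13)
    nu0 = _flat_oracle(l12=1e-300)
    val = sp.p13(nu0, 8.0, 1, 1, w)[0]
    assert abs(val - (1 - np.exp(-0.2 * 8.0))) < 1e-10


@pytest.mark.parametrize("tau", [2.0, 10.0, 25.0])
def test_p13_oracle_quadrature_matches_closed_form(tau):
    nu = _flat_oracle(0.13, 0.05, 0.21)
    got = sp.p13(nu, tau, 1, 1, np.zeros((1, 1)))[0]
    want = closed_form_p13(0.13, 0.05, 0.21, tau)
    assert abs(got - want) < 1e-10


def test_h_weight_boundary_identities():
    nu = _flat_oracle()
    w = np.zeros((1, 1))
    tau = 12.0
    h12, h13, h23 = sp.h_weights(nu, tau, tau, 1, 1, w)
    assert abs(h12[0]) < 1e-12                      # h12(tau) = 0
    assert abs(h13[0] - sp.omega(nu, tau, 1, 1, w)[0]) < 1e-12
    # aD = aI: hazard ratio is one, h23 = Omega_s S2(tau|s)
    s = 4.0
    _, _, h23 = sp.h_weights(nu, s, tau, 1, 1, w)
    assert abs(h23[0] - np.exp(-0.3 * s) * np.exp(-0.15 * (tau - s))) < 1e-12
    # h13(0) = 1 - P13(tau)
    h12, h13, _ = sp.h_weights(nu, 0.0, tau, 0, 1, w)
    assert abs(h13[0] - (1.0 - sp.p13(nu, tau, 0, 1, w)[0])) < 1e-9


def test_h_weights_step_backend_matches_oracle(study1_config, study1_data,
                                               oracle_nuisances, fitted_nuisances):
    """Fitted step h-functions approach the oracle h-functions."""
    w = np.array([[0.5]])
    tau = 15.0
    for s in (0.0, 5.0, 10.0):
        ho = sp.h_weights(oracle_nuisances, s, tau, 1, 0, w)
        hf = sp.h_weights(fitted_nuisances, s, tau, 1, 0, w)
        for a, b in zip(ho, hf):
            assert abs(a[0] - b[0]) < 0.1


def test_eif_indicator_structure(oracle_nuisances, study1_data):
    """Subjects outside both intervention arms contribute only the
    G-computation term; healthy subjects contribute nothing to the 2->3
    term."""
    a = 1
    br = eif_terms(oracle_nuisances, study1_data, 15.0, a, a)
    other = study1_data.treatment == 1 - a
    assert np.all(br.term_m12[other] == 0.0)
    assert np.all(br.term_m13[other] == 0.0)
    assert np.all(br.term_m23[other] == 0.0)
    np.testing.assert_allclose(br.phi[other], br.term_gcomp[other])
    healthy = study1_data.illness == 0
    assert np.all(br.term_m23[healthy] == 0.0)


def test_eif_censored_in_state1_has_no_jump_terms(oracle_nuisances, study1_data):
    # censored in state 1: no counting-process jumps, so each martingale
    # term is minus its compensator, which is <= 0 for positive h weights
    cens1 = (study1_data.illness == 0) & (study1_data.death == 0)
    br = eif_terms(oracle_nuisances, study1_data, 15.0, 1, 1)
    arm = study1_data.treatment == 1
    sel = cens1 & arm
    assert np.all(br.term_m12[sel] <= 0.0)
    assert np.all(br.term_m13[sel] <= 0.0)


def test_one_step_equals_plug_in_plus_martingale_mean(fitted_nuisances, study1_data):
    br = eif_terms(fitted_nuisances, study1_data, 15.0, 1, 0)
    lhs = sp.one_step(fitted_nuisances, study1_data, 15.0, 1, 0)
    rhs = (sp.plug_in(fitted_nuisances, study1_data, 15.0, 1, 0)
           + (br.term_m12 + br.term_m13 + br.term_m23).mean())
    assert abs(lhs - rhs) < 1e-12


def test_plug_in_monotone_in_tau(fitted_nuisances, study1_data):
    taus = np.array([1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0])
    for ad, ai in ((1, 1), (0, 1), (1, 0), (0, 0)):
        vals = sp.plug_in(fitted_nuisances, study1_data, taus, ad, ai)
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all((vals >= 0) & (vals <= 1))


def test_contrast_decomposition_and_ranges(fitted_nuisances, study1_data):
    for est in ("plug_in", "one_step"):
        res = sp.contrasts(fitted_nuisances, study1_data, [5.0, 15.0], est)
        for tau in (5.0, 15.0):
            for a in (0, 1):
                gap = res.te[tau] - res.sde[(tau, a)] - res.sie[(tau, 1 - a)]
                assert abs(gap) < 1e-12
        assert all(-1 <= v <= 1 for v in res.sde.values())
        assert all(-1 <= v <= 1 for v in res.sie.values())


def test_sde_vanishes_without_death_path_treatment_effect(study1_data):
    """Zero treatment coefficients in the 1->3 and 2->3 hazards force
    SDE(tau, aI) = 0 for every tau."""
    cw = np.log(2)
    nu = NuisanceSet(
        lambda12=OracleHazard(0.039, lambda a, W: cw * W[:, 0] + a),
        lambda13=OracleHazard(0.026, lambda a, W: cw * W[:, 0]),
        lambda23=OracleHazard(0.052, lambda a, W: cw * W[:, 0], delayed_entry=True),
        censoring=CensoringModel(None, None),
        propensity=OraclePropensity(lambda W: np.full(W.shape[0], 0.5)),
        provenance="oracle",
    )
    res = sp.contrasts(nu, study1_data, [5.0, 15.0], "plug_in")
    assert all(abs(v) < 1e-12 for v in res.sde.values())


def test_no_censoring_collapse(study1_config):
    """On fully observed data the observed-data EIF equals the full-data
    EIF subject by subject."""
    cfg = sp.SimulationConfig(**{**study1_config.__dict__, "b_c": 1e-9,
                                 "n": 500, "seed": 31})
    data = sp.simulate_observed_study1(cfg)
    assert data.death.mean() == 1.0  # effectively uncensored
    nu = sp.true_nuisances(cfg)  # censoring hazard ~ 0, so K ~ 1
    phi_obs = sp.eif_phi(nu, data, 15.0, 1, 0)
    phi_full = sp.eif_phi(nu, data, 15.0, 1, 0, full_data=True)
    np.testing.assert_allclose(phi_obs, phi_full, atol=1e-6)
    # same collapse for fitted nuisances: degenerate censoring fit => K == 1
    with pytest.warns(UserWarning, match="no censoring"):
        nuf = sp.fit_nuisances(data)
    np.testing.assert_allclose(sp.eif_phi(nuf, data, 15.0, 1, 0),
                               sp.eif_phi(nuf, data, 15.0, 1, 0, full_data=True),
                               atol=1e-12)


def _mixed(base: NuisanceSet, wrong: dict) -> NuisanceSet:
    parts = {"lambda12": base.lambda12, "lambda13": base.lambda13,
             "lambda23": base.lambda23, "censoring": base.censoring,
             "propensity": base.propensity}
    parts.update(wrong)
    return NuisanceSet(**parts, provenance="oracle")


def test_eif_robustness_patterns(study1_config):
    """The EIF estimating function stays unbiased when one transition
    hazard (or the propensity+censoring pair) is replaced by a wrong fixed
    model, and loses unbiasedness outside those patterns."""
    cfg = sp.SimulationConfig(**{**study1_config.__dict__, "n": 20_000, "seed": 57})
    data = sp.simulate_observed_study1(cfg)
    base = sp.true_nuisances(cfg)
    cw = np.log(2)
    wrong12 = OracleHazard(0.08, lambda a, W: 0.3 * W[:, 0] + 0.5 * a)
    wrong13 = OracleHazard(0.05, lambda a, W: 0.2 * W[:, 0])
    wrong23 = OracleHazard(0.03, lambda a, W: 1.5 * W[:, 0] + a, delayed_entry=True)
    wrong_pi = OraclePropensity(lambda W: np.full(W.shape[0], 0.35))
    wrong_c = CensoringModel(
        OracleHazard(0.07, lambda a, W: 0.5 * W[:, 0]),
        OracleHazard(0.07, lambda a, W: 0.5 * W[:, 0], delayed_entry=True))
    truth, tse = sp.true_psi_mc(cfg, 1, 0, 15.0, 400_000, 9)

    ok_patterns = [
        {"lambda13": wrong13},                      # 1->3 wrong
        {"lambda12": wrong12},                      # 1->2 wrong
        {"lambda23": wrong23},                      # 2->3 wrong
        {"propensity": wrong_pi, "censoring": wrong_c},
    ]
    for wrong in ok_patterns:
        phi = sp.eif_phi(_mixed(base, wrong), data, 15.0, 1, 0)
        se = np.sqrt(phi.var(ddof=1) / data.n + tse**2)
        assert abs(phi.mean() - truth) < 3.5 * se, wrong.keys()

    # two wrong state-1 exit hazards break every robustness pattern
    flat = lambda a, W: np.zeros(W.shape[0])
    phi = sp.eif_phi(_mixed(base, {"lambda12": OracleHazard(0.2, flat),
                                   "lambda13": OracleHazard(0.1, flat)}),
                     data, 15.0, 1, 0)
    se = np.sqrt(phi.var(ddof=1) / data.n + tse**2)
    assert abs(phi.mean() - truth) > 3.5 * se
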