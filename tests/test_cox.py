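"""Weighted stratified partial-likelihood engine against independent oracles."""

import numpy as np
import pytest

from survipw import Design1, SurvivalDataset, gen_design1
from survipw.cox import CoxEngine, risk_moments
from survipw.propensity import fit_propensity


def ipw_weights(d):
    fit, _ = fit_propensity(d, terms=["z2", "event"])
    return np.where(d.xi == 1, 1.0 / fit.pi, 0.0)


def naive_score(d, beta, w):
    """O(n^2) double-loop evaluation of the weighted stratified score."""
    Z = np.where(d.mask, d.Z, 0.0)
    total = np.zeros(d.p)
    for i in range(d.n):
        if d.event[i] != 1 or w[i] == 0:
            continue
        at_risk = (d.stratum == d.stratum[i]) & (d.time >= d.time[i])
        r = w[at_risk] * np.exp(Z[at_risk] @ beta)
        s0 = r.sum()
        s1 = r @ Z[at_risk]
        total += w[i] * (Z[i] - s1 / s0)
    return total / d.n


def weighted_logpl(d, beta, w):
    Z = np.where(d.mask, d.Z, 0.0)
    total = 0.0
    for i in range(d.n):
        if d.event[i] != 1 or w[i] == 0:
            continue
        at_risk = (d.stratum == d.stratum[i]) & (d.time >= d.time[i])
        r = w[at_risk] * np.exp(Z[at_risk] @ beta)
        total += w[i] * (Z[i] @ beta - np.log(r.sum()))
    return total / d.n


def test_risk_moments_match_direct_summation(toy):
    w = np.where(toy.xi == 1, 1.0, 0.0)
    beta = np.array([0.5, -0.2])
    Z = np.where(toy.mask, toy.Z, 0.0)
    mom = risk_moments(toy, beta, w)
    for l, (times, S0, S1) in enumerate(mom):
        for k, t in enumerate(times):
            at_risk = (toy.stratum == l) & (toy.time >= t)
            r = w[at_risk] * np.exp(Z[at_risk] @ beta)
            np.testing.assert_allclose(S0[k], r.sum() / toy.n, rtol=1e-12)
            np.testing.assert_allclose(S1[k], r @ Z[at_risk] / toy.n, rtol=1e-12)


def test_risk_moments_mean_covariate_at_beta_zero(toy):
    # with beta = 0 and unit weights S1/S0 is the risk-set mean of Z
    mom = risk_moments(toy, np.zeros(2), np.ones(toy.n))
    Z = np.where(toy.mask, toy.Z, 0.0)
    times, S0, S1 = mom[0]
    t = times[0]
    at_risk = (toy.stratum == 0) & (toy.time >= t)
    np.testing.assert_allclose(S1[0] / S0[0], Z[at_risk].mean(axis=0))


def test_score_matches_naive_double_loop(d1_small):
    w = ipw_weights(d1_small)
    eng = CoxEngine(d1_small)
    for beta in (np.zeros(2), np.array([0.5, 0.5]), np.array([-0.3, 1.0])):
        np.testing.assert_allclose(eng.score(beta, w),
                                   naive_score(d1_small, beta, w), atol=1e-12)


def test_score_matches_numeric_gradient_of_logpl(d1_small):
    w = ipw_weights(d1_small)
    eng = CoxEngine(d1_small)
    beta = np.array([0.3, -0.2])
    h = 1e-6
    g = np.zeros(2)
    for k in range(2):
        e = np.zeros(2)
        e[k] = h
        g[k] = (weighted_logpl(d1_small, beta + e, w)
                - weighted_logpl(d1_small, beta - e, w)) / (2 * h)
    np.testing.assert_allclose(eng.score(beta, w), g, atol=1e-8)


def test_information_matches_numeric_jacobian(d1_small):
    w = ipw_weights(d1_small)
    eng = CoxEngine(d1_small)
    beta = np.array([0.4, 0.1])
    _, info = eng.score_and_information(beta, w)
    h = 1e-5
    J = np.zeros((2, 2))
    for k in range(2):
        e = np.zeros(2)
        e[k] = h
        J[:, k] = (eng.score(beta + e, w) - eng.score(beta - e, w)) / (2 * h)
    np.testing.assert_allclose(info, -J, atol=1e-7)


def test_solve_matches_lifelines_stratified_cox(d1_small):
    from lifelines import CoxPHFitter
    from survipw import complete_cases
    cc = complete_cases(d1_small)
    eng = CoxEngine(cc)
    sol = eng.solve(np.ones(cc.n))
    assert sol.converged
    df = cc.to_frame()
    cph = CoxPHFitter()
    cph.fit(df, "time", "status", strata=["stratum"])
    np.testing.assert_allclose(sol.beta, cph.params_.values, atol=1e-6)


def test_solve_recovers_target_root(d1_small):
    w = ipw_weights(d1_small)
    eng = CoxEngine(d1_small)
    beta0 = np.array([0.25, -0.4])
    target = eng.score(beta0, w)
    sol = eng.solve(w, target=target)
    assert sol.converged
    np.testing.assert_allclose(sol.beta, beta0, atol=1e-7)


def test_integer_weights_equal_record_replication(d1_small):
    toy = d1_small
    rng = np.random.default_rng(3)
    k = rng.integers(1, 4, toy.n).astype(float)
    k[toy.xi == 0] = 0
    rep = np.repeat(np.arange(toy.n), k.astype(int))
    dup = SurvivalDataset(time=toy.time[rep], event=toy.event[rep],
                          stratum=toy.stratum[rep], Z=toy.Z[rep],
                          mask=toy.mask[rep],
                          covariate_names=list(toy.covariate_names))
    beta = np.array([0.2, 0.3])
    e1, e2 = CoxEngine(toy), CoxEngine(dup)
    # raw (unnormalised) scores agree; the 1/n factors differ by design
    np.testing.assert_allclose(e1.score(beta, k) * toy.n,
                               e2.score(beta, np.ones(dup.n)) * dup.n,
                               atol=1e-10)
    s1 = e1.solve(k)
    s2 = e2.solve(np.ones(dup.n))
    np.testing.assert_allclose(s1.beta, s2.beta, atol=1e-7)
    # Breslow increments are normalisation-free and identical
    b1 = e1.breslow(s1.beta, k)
    b2 = e2.breslow(s1.beta, np.ones(dup.n))
    for l in range(2):
        np.testing.assert_allclose(b1.increments[l], b2.increments[l],
                                   atol=1e-12)


def test_location_shift_invariance(d1_small):
    w = ipw_weights(d1_small)
    eng = CoxEngine(d1_small)
    sol = eng.solve(w)
    shifted = SurvivalDataset(
        time=d1_small.time, event=d1_small.event, stratum=d1_small.stratum,
        Z=d1_small.Z + 3.7, mask=d1_small.mask,
        covariate_names=list(d1_small.covariate_names))
    sol2 = CoxEngine(shifted).solve(w)
    np.testing.assert_allclose(sol.beta, sol2.beta, atol=1e-6)


def test_breslow_single_event_is_nelson_aalen():
    d = SurvivalDataset(time=np.array([1.0, 2.0, 3.0]),
                        event=np.array([0, 1, 0]),
                        stratum=np.zeros(3, int),
                        Z=np.zeros((3, 1)), mask=np.ones((3, 1), bool))
    base = CoxEngine(d).breslow(np.zeros(1), np.ones(3))
    # two subjects at risk at t=2
    np.testing.assert_allclose(base.increments[0], [0.5])


def test_breslow_no_events_is_empty():
    d = SurvivalDataset(time=np.array([1.0, 2.0]), event=np.array([0, 0]),
                        stratum=np.zeros(2, int), Z=np.zeros((2, 1)),
                        mask=np.ones((2, 1), bool))
    base = CoxEngine(d).breslow(np.zeros(1), np.ones(2))
    assert len(base.times[0]) == 0


def test_weighted_martingale_residuals_sum_to_zero(d1_small):
    """Under the IPW Breslow form, sum_i w_i M-hat_i(tau) = 0 per stratum."""
    w = ipw_weights(d1_small)
    eng = CoxEngine(d1_small)
    beta = eng.solve(w).beta
    base = eng.breslow(beta, w)
    Z = np.where(d1_small.mask, d1_small.Z, 0.0)
    for l in range(2):
        t_l, cum = base.cumulative(l)
        sel = d1_small.stratum == l
        idx = np.searchsorted(t_l, d1_small.time[sel], side="right") - 1
        Lam = np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
        M = d1_small.event[sel] - np.exp(Z[sel] @ beta) * Lam
        assert abs(np.sum(w[sel] * M)) < 1e-8


def test_residuals_match_naive_double_loop(toy):
    w = np.where(toy.xi == 1, 1.0, 0.0)
    beta = np.array([0.3, -0.1])
    eng = CoxEngine(toy)
    res = eng.integrated_score_residuals(beta, w)
    base = eng.breslow(beta, w)
    Z = np.where(toy.mask, toy.Z, 0.0)
    for i in range(toy.n):
        if w[i] == 0:
            continue
        l = toy.stratum[i]
        t_l, dL = base.times[l], base.increments[l]
        expect = np.zeros(2)
        # event term
        if toy.event[i] == 1:
            at_risk = (toy.stratum == l) & (toy.time >= toy.time[i])
            r = w[at_risk] * np.exp(Z[at_risk] @ beta)
            expect += Z[i] - (r @ Z[at_risk]) / r.sum()
        # drift over stratum event times up to X_i
        for k, t in enumerate(t_l):
            if t > toy.time[i]:
                break
            at_risk = (toy.stratum == l) & (toy.time >= t)
            r = w[at_risk] * np.exp(Z[at_risk] @ beta)
            ebar = (r @ Z[at_risk]) / r.sum()
            expect -= np.exp(Z[i] @ beta) * (Z[i] - ebar) * dL[k]
        np.testing.assert_allclose(res[i], expect, atol=1e-12)


def test_residuals_sum_to_score_identity(d1_small):
    """sum_i w_i resid_i = n U1(beta) at any beta (algebraic identity)."""
    w = ipw_weights(d1_small)
    eng = CoxEngine(d1_small)
    beta = np.array([0.5, 0.4])
    res = eng.integrated_score_residuals(beta, w)
    lhs = (w[:, None] * res).sum(axis=0)
    rhs = eng.score(beta, w) * d1_small.n
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_censored_subject_before_all_events_has_zero_residual():
    d = SurvivalDataset(time=np.array([0.5, 2.0, 3.0, 4.0]),
                        event=np.array([0, 1, 1, 0]),
                        stratum=np.zeros(4, int),
                        Z=np.arange(4.0)[:, None],
                        mask=np.ones((4, 1), bool))
    res = CoxEngine(d).integrated_score_residuals(np.zeros(1), np.ones(4))
    np.testing.assert_allclose(res[0], 0.0)


def test_solve_flags_divergence():
    # monotone likelihood: the single covariate perfectly orders event times
    d = SurvivalDataset(time=np.array([1.0, 2.0, 3.0, 4.0]),
                        event=np.array([1, 1, 1, 1]),
                        stratum=np.zeros(4, int),
                        Z=np.array([[3.0], [2.0], [1.0], [0.0]]),
                        mask=np.ones((4, 1), bool))
    sol = CoxEngine(d).solve(np.ones(4), beta_bound=10.0)
    assert not sol.converged


def test_dscore_dweights_matches_finite_differences(d1_small):
    from survipw.propensity import build_response_design
    fitw, design = fit_propensity(d1_small, terms=["z2", "event"])
    xi = d1_small.xi
    w = np.where(xi == 1, 1.0 / fitw.pi, 0.0)
    eng = CoxEngine(d1_small)
    beta = eng.solve(w).beta
    gw = -(w * (1 - fitw.pi))[:, None] * design.omega
    analytic = eng.dscore_dweights(beta, w, gw)
    from scipy.special import expit
    h = 1e-6
    fd = np.zeros_like(analytic)
    for k in range(design.q):
        e = np.zeros(design.q)
        e[k] = h
        wp = np.where(xi == 1, 1.0 / expit(design.omega @ (fitw.phi + e)), 0.0)
        wm = np.where(xi == 1, 1.0 / expit(design.omega @ (fitw.phi - e)), 0.0)
        fd[:, k] = (eng.score(beta, wp) - eng.score(beta, wm)) / (2 * h)
    np.testing.assert_allclose(analytic, fd, atol=1e-5)


def test_ipw_estimate_near_truth_on_large_design1():
    d = gen_design1(Design1(n=2000, event_rate=0.7), seed=777)
    from survipw import fit_ipw
    r = fit_ipw(d, terms=["z2", "event"])
    # truth log 2; Monte-Carlo tolerance ~3 SE
    assert np.all(np.abs(r.beta - np.log(2)) < 3.5 * r.se)
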