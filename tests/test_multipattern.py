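"""Multiple-missing-pattern propensities, scores and estimation."""

import numpy as np
import pytest

from survipw import (Design2, PatternDataset, fit_cc, fit_ipw, fit_multi_ipw,
                     gen_design2)
from survipw.cox import CoxEngine
from survipw.multipattern import (PATTERN_KEYS, build_pattern_designs,
                                  propensities, score_Uab, sigma_m, solve_Uab)

TERMS = dict(terms10=["event", "z1", "z3"], terms01=["event", "z2", "z3"],
             terms00=["event", "z3"])


@pytest.fixture(scope="module")
def designs(d2_small):
    return build_pattern_designs(d2_small, **TERMS)


@pytest.fixture(scope="module")
def zero_phis(designs):
    return {k: np.zeros(designs.q(k)) for k in PATTERN_KEYS}


def test_category_bookkeeping(d2_small):
    counts = d2_small.category_counts()
    assert counts.sum() == d2_small.n
    xi = d2_small.xi
    np.testing.assert_array_equal(xi, (d2_small.category == 0).astype(int))
    np.testing.assert_array_equal(xi, d2_small.eta1 * d2_small.eta2)


def test_uniform_propensities_at_zero_coefficients(d2_small, designs, zero_phis):
    prop = propensities(d2_small, zero_phis, designs)
    full = d2_small.xi == 1
    np.testing.assert_allclose(prop.pi[full], 0.25)


def test_propensities_sum_to_one_for_fully_observed(d2_small, designs):
    rng = np.random.default_rng(4)
    phis = {k: rng.normal(0, 0.5, designs.q(k)) for k in PATTERN_KEYS}
    prop = propensities(d2_small, phis, designs)
    full = d2_small.xi == 1
    np.testing.assert_allclose(prop.pi[full].sum(axis=1), 1.0, atol=1e-12)
    assert np.all((prop.pi[full] > 0) & (prop.pi[full] < 1))


def test_large_negative_intercept_empties_a_pattern(d2_small, designs, zero_phis):
    phis = {k: v.copy() for k, v in zero_phis.items()}
    phis["00"][0] = -40.0
    prop = propensities(d2_small, phis, designs)
    full = d2_small.xi == 1
    np.testing.assert_allclose(prop.pi[full, 3], 0.0, atol=1e-15)
    np.testing.assert_allclose(prop.pi[full, :3], 1 / 3, atol=1e-12)


def test_score_Uab_zero_at_conditional_logistic_mle(d2_small, designs):
    for key in PATTERN_KEYS:
        phi, conv, _ = solve_Uab(d2_small, key, designs)
        assert conv
        assert np.max(np.abs(score_Uab(d2_small, phi, key, designs))) < 1e-9


def test_score_Uab_equals_single_pattern_logistic_score(d2_small, designs):
    """U_ab is the logistic score of xi on omega_ab (negated coefficients)
    over the pooled pair, up to the 1/N_ab vs 1/n_pair normalisation."""
    from survipw.propensity import ResponseDesign, score_U2
    key = "01"
    sel = (d2_small.category == 2) | (d2_small.category == 0)
    om = designs.omega[key][sel]
    xi_pair = (d2_small.category[sel] == 0).astype(int)
    rd = ResponseDesign(omega=om, column_names=designs.column_names[key])
    rng = np.random.default_rng(6)
    phi = rng.normal(0, 0.3, om.shape[1])
    n_pair = sel.sum()
    N_ab = int((d2_small.category == 2).sum())
    lhs = score_Uab(d2_small, phi, key, designs)
    rhs = score_U2(-phi, rd, xi_pair) * n_pair / N_ab
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_score_Uab_matches_numeric_gradient(d2_small, designs):
    """Central differences of the pooled-pair Bernoulli log-likelihood."""
    key = "10"
    sel = (d2_small.category == 1) | (d2_small.category == 0)
    om = designs.omega[key][sel]
    xi = (d2_small.category[sel] == 0).astype(float)
    N_ab = int((d2_small.category == 1).sum())

    def loglik(phi):
        lp = -(om @ phi)
        return float(np.sum(xi * lp - np.log1p(np.exp(lp)))) / N_ab

    rng = np.random.default_rng(7)
    phi = rng.normal(0, 0.3, om.shape[1])
    h = 1e-6
    g = np.zeros_like(phi)
    for k in range(len(phi)):
        e = np.zeros_like(phi)
        e[k] = h
        g[k] = (loglik(phi + e) - loglik(phi - e)) / (2 * h)
    # d loglik / d phi = -score contribution => negate
    np.testing.assert_allclose(score_Uab(d2_small, phi, key, designs), -g,
                               atol=1e-6)


def test_U1m_delegates_to_weighted_cox_score(d2_small, designs):
    phis = {}
    for key in PATTERN_KEYS:
        phis[key], _, _ = solve_Uab(d2_small, key, designs)
    prop = propensities(d2_small, phis, designs)
    xi = d2_small.xi
    w = np.where(xi == 1, 1.0 / prop.pi11, 0.0)
    eng = CoxEngine(d2_small)
    beta = np.array([0.3, 0.3, -0.3])
    # identical contract to the single-pattern engine with weights xi/pi11
    s1 = eng.score(beta, w)
    s2 = eng.score(beta, np.where(xi == 1, 1.0 / prop.pi11, 0.0))
    np.testing.assert_allclose(s1, s2)
    # pi11 = 1 reduces to the classical complete-case score
    s_cc = eng.score(beta, xi.astype(float))
    s_unit = eng.score(beta, np.where(xi == 1, 1.0, 0.0))
    np.testing.assert_allclose(s_cc, s_unit)


def test_block_jacobian_is_block_diagonal(d2_small, designs):
    """dU_ab/dphi_a'b' vanishes across patterns (numerically)."""
    rng = np.random.default_rng(8)
    phis = {k: rng.normal(0, 0.2, designs.q(k)) for k in PATTERN_KEYS}
    h = 1e-6
    for ki in PATTERN_KEYS:
        for kj in PATTERN_KEYS:
            if ki == kj:
                continue
            e = np.zeros(designs.q(kj))
            e[0] = h
            up = dict(phis)
            up[kj] = phis[kj] + e
            dn = dict(phis)
            dn[kj] = phis[kj] - e
            diff = (score_Uab(d2_small, up[ki], ki, designs)
                    - score_Uab(d2_small, dn[ki], ki, designs)) / (2 * h)
            np.testing.assert_allclose(diff, 0.0, atol=1e-12)


def test_sigma_m_symmetric_psd(d2_small, designs):
    phis = {k: solve_Uab(d2_small, k, designs)[0] for k in PATTERN_KEYS}
    r = fit_multi_ipw(d2_small, **TERMS)
    S = r.sigma
    J = S.joint
    np.testing.assert_allclose(J, J.T, atol=1e-14)
    assert np.linalg.eigvalsh(S.sigma_cm).min() >= -1e-15
    assert np.linalg.eigvalsh(S.var_U2m).min() >= -1e-12


def test_reduction_to_single_pattern_when_only_11_and_00(d2_small):
    """With patterns 10 and 01 empty the multi-pattern estimator equals the
    single-pattern IPW estimator with the omega_00 response design."""
    d = d2_small
    cat = d.category
    keep = np.isin(cat, (0, 3))
    # rebuild with patterns 10/01 converted to 00 (drop their half-observed values)
    mask = d.mask.copy()
    mask[~keep, 0] = False
    mask[~keep, 1] = False
    Z = np.where(mask, np.where(np.isnan(d.Z), 0.0, d.Z), np.nan)
    dd = PatternDataset(time=d.time, event=d.event, stratum=d.stratum, Z=Z,
                        mask=mask, covariate_names=list(d.covariate_names),
                        stratum_labels=list(d.stratum_labels),
                        missing_idx=(0, 1))
    r_multi = fit_multi_ipw(dd, terms10=["event", "z3"], terms01=["event", "z3"],
                            terms00=["event", "z3"])
    r_single = fit_ipw(dd, terms=["event", "z3"])
    np.testing.assert_allclose(r_multi.beta, r_single.beta, atol=1e-8)


def test_all_observed_degenerate_methods_coincide():
    cfg = Design2(n=600, phi10=(-40, 0, 0, 0, 0), phi01=(-40, 0, 0, 0, 0),
                  phi00=(-40, 0, 0, 0))
    d = gen_design2(cfg, seed=99)
    assert d.xi.all()
    r_cc = fit_cc(d)
    r_mm = fit_multi_ipw(d, **TERMS)
    r_sm = fit_ipw(d, terms=["event", "z3"])
    np.testing.assert_allclose(r_mm.beta, r_cc.beta, atol=1e-6)
    np.testing.assert_allclose(r_sm.beta, r_cc.beta, atol=1e-6)


def test_pattern_design_rejects_wrong_missing_covariate(d2_small):
    with pytest.raises(ValueError, match="z2"):
        build_pattern_designs(d2_small, terms10=["event", "z2"])
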