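"""Sigma-hat blocks, Schur complement and the joint sandwich variance."""

import numpy as np
import pytest

from survipw import fit_ipw
from survipw.cox import CoxEngine
from survipw.data import SurvivalDataset
from survipw.propensity import ResponseDesign, build_response_design, score_U2
from survipw.variance import (cov_U1_U2, sandwich_variance, sigma_blocks,
                              sigma_c, var_U1)


@pytest.fixture(scope="module")
def fitted(d1_small):
    return fit_ipw(d1_small, terms=["z2", "event"])


def test_var_U1_matches_naive_outer_products(d1_small, fitted):
    eng = fitted.engine
    w = np.where(d1_small.xi == 1, 1.0 / fitted.pi, 0.0)
    resid = eng.integrated_score_residuals(fitted.beta, w)
    naive = np.zeros((2, 2))
    for i in range(d1_small.n):
        if d1_small.xi[i] == 1:
            naive += np.outer(resid[i], resid[i]) / fitted.pi[i] ** 2
    naive /= d1_small.n ** 2
    np.testing.assert_allclose(var_U1(d1_small, resid, fitted.pi), naive,
                               atol=1e-14)


def test_var_U1_zero_when_residuals_zero(d1_small, fitted):
    V = var_U1(d1_small, np.zeros((d1_small.n, 2)), fitted.pi)
    np.testing.assert_allclose(V, 0.0)


def test_var_U1_rejects_zero_pi_for_complete_case(d1_small):
    pi = np.ones(d1_small.n)
    pi[np.flatnonzero(d1_small.xi == 1)[0]] = 0.0
    with pytest.raises(ValueError, match="zero"):
        var_U1(d1_small, np.zeros((d1_small.n, 2)), pi)


def test_cov_block_vanishes_without_missingness(d1_small, fitted):
    resid = fitted.engine.integrated_score_residuals(
        fitted.beta, np.where(d1_small.xi == 1, 1.0, 0.0))
    C = cov_U1_U2(d1_small, resid, np.ones(d1_small.n), fitted.design)
    np.testing.assert_allclose(C, 0.0)


def test_cov_block_hand_computed_rank_one():
    # three subjects, one complete case with a known residual
    d = SurvivalDataset(time=np.array([1.0, 2.0, 3.0]),
                        event=np.array([1, 1, 0]),
                        stratum=np.zeros(3, int),
                        Z=np.array([[1.0], [2.0], [0.5]]),
                        mask=np.ones((3, 1), bool))
    design = ResponseDesign(omega=np.ones((3, 1)), column_names=["intercept"])
    resid = np.array([[0.4], [-0.1], [0.2]])
    pi = np.array([0.5, 0.8, 0.9])
    C = cov_U1_U2(d, resid, pi, design)
    expect = sum((1 - pi[i]) / pi[i] * resid[i, 0] for i in range(3)) / 9.0
    np.testing.assert_allclose(C, [[expect]])


def test_schur_complement_scalar_formula():
    a, b, c = 2.0, 3.0, 1.5
    S = sigma_c(np.array([[a]]), np.array([[b]]), np.array([[c]]))
    np.testing.assert_allclose(S, [[a - c * c / b]])


def test_schur_identity_when_cov_zero():
    v1 = np.array([[2.0, 0.3], [0.3, 1.0]])
    S = sigma_c(v1, np.eye(3), np.zeros((2, 3)))
    np.testing.assert_allclose(S, v1)


def test_schur_complement_psd_for_random_blocks():
    rng = np.random.default_rng(5)
    for _ in range(20):
        A = rng.normal(size=(5, 5))
        J = A @ A.T + 1e-3 * np.eye(5)  # joint PSD covariance
        S = sigma_c(J[:2, :2], J[2:, 2:], J[:2, 2:])
        assert np.linalg.eigvalsh(S).min() >= -1e-12
        np.testing.assert_allclose(S, S.T)


def test_sigma_blocks_structure(d1_small, fitted):
    blocks = fitted.blocks
    assert np.linalg.eigvalsh(blocks.var_U1).min() >= -1e-15
    assert np.linalg.eigvalsh(blocks.var_U2).min() >= -1e-15
    # Sigma_c <= Var(U1) in the PSD order
    diff = blocks.var_U1 - blocks.sigma_c
    assert np.linalg.eigvalsh(diff).min() >= -1e-12
    # assembled joint matrix is symmetric with matching cross blocks
    J = blocks.joint
    np.testing.assert_allclose(J, J.T)
    np.testing.assert_allclose(J[:2, 2:], blocks.cov_U1_U2)


def test_bread_matches_finite_difference_jacobian(d1_small, fitted):
    """Analytic Jacobian of the joint score vs central differences."""
    from scipy.special import expit
    d = d1_small
    design = fitted.design
    eng = fitted.engine
    q, p = design.q, d.p
    theta = np.concatenate([fitted.beta, fitted.phi])

    def joint_score(th):
        beta, phi = th[:p], th[p:]
        pi = expit(design.omega @ phi)
        w = np.where(d.xi == 1, 1.0 / pi, 0.0)
        return np.concatenate([eng.score(beta, w),
                               score_U2(phi, design, d.xi)])

    h = 1e-6
    fd = np.zeros((p + q, p + q))
    for k in range(p + q):
        e = np.zeros(p + q)
        e[k] = h
        fd[:, k] = (joint_score(theta + e) - joint_score(theta - e)) / (2 * h)
    np.testing.assert_allclose(fitted.sandwich.bread, fd, atol=1e-5)


def test_sandwich_psd_with_positive_diagonal(fitted):
    V = fitted.sandwich.covariance
    assert np.linalg.eigvalsh(V).min() >= -1e-15
    assert np.all(np.diag(V) > 0)
    np.testing.assert_allclose(fitted.se, np.sqrt(np.diag(V)[:2]))


def test_known_pi_variance_dominates_estimated_pi(d1_mid):
    """Estimating the propensity reduces the IPW variance (PSD order)."""
    r = fit_ipw(d1_mid, terms=["z2", "event"])
    V_known = sandwich_variance(d1_mid, r.beta, r.phi, r.pi, r.design,
                                blocks=r.blocks, engine=r.engine,
                                known_pi=True).covariance
    V_est = r.sandwich.beta_covariance
    diff = V_known - V_est
    assert np.linalg.eigvalsh(diff).min() >= -1e-10


def test_var_U1_scale_stabilises_across_seeds():
    """n * Var-hat(U1) is an O(1) quantity: relative spread < 10%."""
    from survipw import Design1, gen_design1
    traces = []
    for s in range(20):
        d = gen_design1(Design1(n=2000, event_rate=0.7), seed=3000 + s)
        r = fit_ipw(d, terms=["z2", "event"])
        traces.append(np.trace(r.blocks.var_U1) * d.n)
    traces = np.asarray(traces)
    assert traces.std() / traces.mean() < 0.10
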