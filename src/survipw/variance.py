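"""Joint score covariance and sandwich variance, single missingness pattern.

The joint estimating function is theta = (beta, phi) |-> (U1, U2).  Its
estimated covariance on the per-dataset scale is assembled from per-subject
pieces:

    Var(U1)     = (1/n^2) sum xi/pi^2 [integrated score residual]^(x)2
    Cov(U1,U2)  = (1/n^2) sum xi(1-pi)/pi [residual] omega'
    Var(U2)     = (1/n^2) sum pi(1-pi) omega omega'

The Schur complement Sigma_c = Var(U1) - Cov Var(U2)^{-1} Cov' is the
perturbation covariance the posterior sampler draws eta1* from; it is
symmetrised and eigenvalue-floored so the normal draw is always defined.

The frequentist variance of theta-hat is the sandwich B^{-1} Sigma B^{-T}
with bread B the analytic Jacobian of the joint score at theta-hat:
dU1/dbeta = -(weighted information), dU1/dphi through
d(xi/pi)/dphi = -(xi/pi)(1-pi) omega, dU2/dbeta = 0 and dU2/dphi =
-(Fisher information)/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cox import CoxEngine
from .data import SurvivalDataset
from .propensity import ResponseDesign, var_U2

__all__ = [
    "SigmaBlocks",
    "SandwichVariance",
    "var_U1",
    "cov_U1_U2",
    "sigma_c",
    "sigma_blocks",
    "sandwich_variance",
]

EIGEN_FLOOR_REL = 1e-12


@dataclass
class SigmaBlocks:
    var_U1: np.ndarray      # (p, p)
    var_U2: np.ndarray      # (q, q)
    cov_U1_U2: np.ndarray   # (p, q)
    sigma_c: np.ndarray     # (p, p) Schur complement, floored PSD
    n_floored: int = 0

    @property
    def joint(self) -> np.ndarray:
        """Full (p+q) x (p+q) covariance of (U1, U2)."""
        top = np.hstack([self.var_U1, self.cov_U1_U2])
        bot = np.hstack([self.cov_U1_U2.T, self.var_U2])
        return np.vstack([top, bot])


@dataclass
class SandwichVariance:
    covariance: np.ndarray  # Var(theta-hat), (p+q) x (p+q)
    bread: np.ndarray
    meat: np.ndarray
    p: int

    @property
    def beta_covariance(self) -> np.ndarray:
        return self.covariance[: self.p, : self.p]

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_covariance))


def _check_pi(pi, xi):
    pi = np.asarray(pi, dtype=float)
    if np.any((np.asarray(xi) == 1) & (pi <= 0)):
        raise ValueError("fitted probability pi is zero for a complete case")
    return pi


def var_U1(d: SurvivalDataset, residuals: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """(1/n^2) sum xi/pi^2 resid resid' from precomputed residual rows."""
    xi = d.xi
    pi = _check_pi(pi, xi)
    w2 = np.where(xi == 1, xi / np.clip(pi, 1e-300, None) ** 2, 0.0)
    R = residuals * np.sqrt(w2)[:, None]
    V = R.T @ R / d.n**2
    return 0.5 * (V + V.T)


def cov_U1_U2(d: SurvivalDataset, residuals: np.ndarray, pi: np.ndarray,
              design: ResponseDesign) -> np.ndarray:
    """(1/n^2) sum xi(1-pi)/pi resid omega'."""
    xi = d.xi
    pi = _check_pi(pi, xi)
    c = np.where(xi == 1, (1.0 - pi) / np.clip(pi, 1e-300, None), 0.0)
    return (residuals * c[:, None]).T @ design.omega / d.n**2


def _floor_psd(M: np.ndarray, rel: float = EIGEN_FLOOR_REL):
    """Symmetrise and floor eigenvalues at rel * trace; returns (M, n_floored)."""
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    floor = rel * max(np.trace(M), 0.0)
    n_floored = int((vals < floor).sum())
    if n_floored:
        vals = np.maximum(vals, floor)
        M = (vecs * vals) @ vecs.T
        M = 0.5 * (M + M.T)
    return M, n_floored


def sigma_c(blocks_or_var1, var2=None, cov12=None) -> np.ndarray:
    """Schur complement Var(U1) - Cov Var(U2)^{-1} Cov', floored PSD."""
    if isinstance(blocks_or_var1, SigmaBlocks):
        v1, v2, c12 = (blocks_or_var1.var_U1, blocks_or_var1.var_U2,
                       blocks_or_var1.cov_U1_U2)
    else:
        v1, v2, c12 = blocks_or_var1, var2, cov12
    try:
        sol = np.linalg.solve(v2, c12.T)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(v2) @ c12.T
    S = v1 - c12 @ sol
    S, _ = _floor_psd(S)
    return S


def sigma_blocks(d: SurvivalDataset, beta, phi, pi, design: ResponseDesign,
                 engine: CoxEngine | None = None) -> SigmaBlocks:
    """Assemble all blocks of Sigma-hat at (beta, phi)."""
    engine = engine or CoxEngine(d)
    xi = d.xi
    pi = _check_pi(pi, xi)
    w = np.where(xi == 1, xi / np.clip(pi, 1e-300, None), 0.0)
    resid = engine.integrated_score_residuals(np.asarray(beta, float), w)
    v1 = var_U1(d, resid, pi)
    v2 = var_U2(phi, design)
    c12 = cov_U1_U2(d, resid, pi, design)
    try:
        sol = np.linalg.solve(v2, c12.T)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(v2) @ c12.T
    S, n_floored = _floor_psd(v1 - c12 @ sol)
    return SigmaBlocks(var_U1=v1, var_U2=v2, cov_U1_U2=c12, sigma_c=S,
                       n_floored=n_floored)


def sandwich_variance(d: SurvivalDataset, beta, phi, pi,
                      design: ResponseDesign, blocks: SigmaBlocks | None = None,
                      engine: CoxEngine | None = None,
                      known_pi: bool = False) -> SandwichVariance:
    """Sandwich Var(theta-hat) = B^{-1} Sigma-hat B^{-T} at theta-hat.

    With ``known_pi=True`` the phi block is dropped: the variance reduces to
    I^{-1} Var(U1) I^{-1}, the known-propensity form (which dominates the
    estimated-propensity variance in the PSD order).
    """
    engine = engine or CoxEngine(d)
    beta = np.asarray(beta, dtype=float)
    xi = d.xi
    pi = _check_pi(pi, xi)
    w = np.where(xi == 1, xi / np.clip(pi, 1e-300, None), 0.0)
    if blocks is None:
        blocks = sigma_blocks(d, beta, phi, pi, design, engine=engine)
    p = d.p
    _, info = engine.score_and_information(beta, w)
    if known_pi:
        Ii = np.linalg.inv(info)
        V = Ii @ blocks.var_U1 @ Ii
        return SandwichVariance(covariance=V, bread=-info, meat=blocks.var_U1, p=p)
    q = design.q
    # dU1/dphi through dw/dphi = -(xi/pi)(1-pi) omega
    gw = -(w * (1.0 - pi))[:, None] * design.omega
    dU1_dphi = engine.dscore_dweights(beta, w, gw)
    pifit = expit(design.omega @ np.asarray(phi, float))
    dU2_dphi = -(design.omega * (pifit * (1 - pifit))[:, None]).T @ design.omega / d.n
    B = np.zeros((p + q, p + q))
    B[:p, :p] = -info
    B[:p, p:] = dU1_dphi
    B[p:, p:] = dU2_dphi
    try:
        Bi = np.linalg.inv(B)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular bread matrix in sandwich variance (information or "
            "Fisher block not invertible)") from e
    V = Bi @ blocks.joint @ Bi.T
    V = 0.5 * (V + V.T)
    return SandwichVariance(covariance=V, bread=B, meat=blocks.joint, p=p)
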