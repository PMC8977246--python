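"""Two missingness-prone covariates with pattern-specific mechanisms.

Subjects fall into four observation categories according to which of the two
designated covariates are observed: 11 (both), 10 (first only), 01 (second
only), 00 (neither).  Each non-reference category has its own log-ratio
model relative to the fully observed category,

    r_ab(Z, O) = P(eta1=a, eta2=b | Z, O) / P(eta=11 | Z, O)
               = exp(phi_ab' omega_ab),      r_11 = 1,

so the propensities are pi_ab = r_ab / (1 + r_10 + r_01 + r_00).  The
design omega_ab may include the covariate that is observed within its own
comparison pair (omega_10 may use the first missingness-prone covariate,
omega_01 the second, omega_00 neither).

Estimation: each phi_ab solves a conditional logistic score U_ab over the
pooled pair {category ab, category 11} — P(fully observed | pair) =
1/(1 + exp(phi_ab' omega_ab)) — and beta solves the IPW Cox score with
weights xi / pi_11.  The block covariance Sigma_m and its Schur complement
drive both the sandwich variance and the approximate-Bayesian sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cox import CoxEngine
from .data import PatternDataset
from .variance import _floor_psd, var_U1

__all__ = [
    "PatternDesigns",
    "active_patterns",
    "MultiPropensity",
    "build_pattern_designs",
    "propensities",
    "score_Uab",
    "solve_Uab",
    "var_Uab",
    "sigma_m",
    "MultiSigma",
    "sandwich_variance_multi",
    "draw_posterior_multi",
]

PATTERN_KEYS = ("10", "01", "00")
CATEGORY_OF = {"11": 0, "10": 1, "01": 2, "00": 3}

NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 100


@dataclass
class PatternDesigns:
    """Design matrices omega_10, omega_01, omega_00 (n x q_ab each).

    Rows referencing an unobserved covariate are NaN; they are only ever
    used inside the comparison pair where the covariate is observed.
    """

    omega: dict           # key -> (n, q_ab) array
    column_names: dict    # key -> list of str

    def q(self, key: str) -> int:
        return self.omega[key].shape[1]

    @property
    def q_total(self) -> int:
        return sum(self.omega[k].shape[1] for k in PATTERN_KEYS)

    def slices(self) -> dict:
        out, start = {}, 0
        for k in PATTERN_KEYS:
            out[k] = slice(start, start + self.q(k))
            start += self.q(k)
        return out


@dataclass
class MultiPropensity:
    """pi_ab per subject; NaN where not computable from observed data."""

    pi: np.ndarray  # (n, 4) columns in category order 11, 10, 01, 00

    @property
    def pi11(self) -> np.ndarray:
        return self.pi[:, 0]


def _term_column(d: PatternDataset, t: str) -> np.ndarray:
    if t == "event":
        return d.event.astype(float)
    if t == "time":
        return d.time
    if t in d.covariate_names:
        j = d.covariate_names.index(t)
        col = np.where(d.mask[:, j], d.Z[:, j], np.nan)
        return col
    raise ValueError(f"unknown pattern-model term {t!r}")


def build_pattern_designs(d: PatternDataset, terms10=None, terms01=None,
                          terms00=None) -> PatternDesigns:
    """Build the three pattern designs, each (intercept, terms, strata).

    Defaults follow the ratio-model convention: omega_10 = (1, Z1m, O),
    omega_01 = (1, Z2m, O), omega_00 = (1, O) with O = (event, time, fully
    observed covariates) plus stratum indicators.
    """
    m1 = d.covariate_names[d.missing_idx[0]]
    m2 = d.covariate_names[d.missing_idx[1]]
    fully = [name for j, name in enumerate(d.covariate_names)
             if j not in d.missing_idx]
    O = ["event", "time"] + fully
    defaults = {"10": [m1] + O, "01": [m2] + O, "00": list(O)}
    given = {"10": terms10, "01": terms01, "00": terms00}
    omega, names = {}, {}
    for key in PATTERN_KEYS:
        terms = defaults[key] if given[key] is None else list(given[key])
        allowed_missing = {"10": {m1}, "01": {m2}, "00": set()}[key]
        bad = (set(terms) & {m1, m2}) - allowed_missing
        if bad:
            raise ValueError(
                f"omega_{key} may not reference missingness-prone covariate(s) "
                f"{sorted(bad)}"
            )
        cols = [np.ones(d.n)]
        cn = ["intercept"]
        for t in terms:
            cols.append(_term_column(d, t))
            cn.append(t)
        for code in range(1, d.n_strata):
            cols.append((d.stratum == code).astype(float))
            cn.append(f"stratum[{d.stratum_labels[code]!r}]")
        omega[key] = np.column_stack(cols)
        names[key] = cn
    return PatternDesigns(omega=omega, column_names=names)


def propensities(d: PatternDataset, phis: dict,
                 designs: PatternDesigns) -> MultiPropensity:
    """pi_ab = r_ab / (1 + r_10 + r_01 + r_00) wherever computable.

    For fully observed subjects all four probabilities are finite and sum
    to one exactly; elsewhere entries needing an unobserved covariate are
    NaN (they are never used by the estimating equations).
    """
    r = np.ones((d.n, 4))
    for key in PATTERN_KEYS:
        ph = phis.get(key)
        if ph is None:
            # empty pattern: its ratio is identically zero
            r[:, CATEGORY_OF[key]] = 0.0
            continue
        lp = designs.omega[key] @ np.asarray(ph, dtype=float)
        r[:, CATEGORY_OF[key]] = np.exp(lp)
    den = np.nansum(r, axis=1) + np.where(np.isnan(r).any(axis=1), np.nan, 0.0)
    return MultiPropensity(pi=r / den[:, None])


def active_patterns(d: PatternDataset, phis: dict | None = None):
    """Pattern keys that occur in the data (and, if given, have coefficients)."""
    keys = [k for k in PATTERN_KEYS
            if (d.category == CATEGORY_OF[k]).any()]
    if phis is not None:
        keys = [k for k in keys if phis.get(k) is not None]
    return keys


def _active_slices(designs, keys):
    out, start = {}, 0
    for k in keys:
        out[k] = slice(start, start + designs.q(k))
        start += designs.q(k)
    return out, start


def _pair_mask(d: PatternDataset, key: str) -> np.ndarray:
    cat = d.category
    return (cat == CATEGORY_OF[key]) | (cat == 0)


def _pair_prob(phi_ab, omega_ab):
    """P(fully observed | comparison pair) = expit(-phi_ab' omega_ab)."""
    return expit(-(omega_ab @ np.asarray(phi_ab, dtype=float)))


def score_Uab(d: PatternDataset, phi_ab, key: str,
              designs: PatternDesigns) -> np.ndarray:
    """(1/N_ab) sum over the pair of {xi - pi11/(pi11+pi_ab)} omega_ab."""
    if key not in PATTERN_KEYS:
        raise ValueError(f"pattern must be one of {PATTERN_KEYS}, got {key!r}")
    sel = _pair_mask(d, key)
    N_ab = int((d.category == CATEGORY_OF[key]).sum())
    if N_ab == 0:
        raise ValueError(f"no subjects in pattern {key}")
    om = designs.omega[key][sel]
    if np.any(~np.isfinite(om)):
        raise ValueError(
            f"design omega_{key} has non-finite entries inside its comparison "
            "pair (a referenced covariate is unobserved)")
    xi = (d.category[sel] == 0).astype(float)
    p = _pair_prob(phi_ab, om)
    return om.T @ (xi - p) / N_ab


def solve_Uab(d: PatternDataset, key: str, designs: PatternDesigns,
              target=None, init=None, tol: float = NEWTON_TOL,
              max_iter: int = NEWTON_MAX_ITER):
    """Solve U_ab(phi_ab) = target by damped Newton; target 0 is the
    conditional-logistic MLE for the pooled pair."""
    sel = _pair_mask(d, key)
    N_ab = int((d.category == CATEGORY_OF[key]).sum())
    om = designs.omega[key][sel]
    xi = (d.category[sel] == 0).astype(float)
    qk = om.shape[1]
    target = np.zeros(qk) if target is None else np.asarray(target, float)
    phi = np.zeros(qk) if init is None else np.asarray(init, float).copy()

    def score(ph):
        return om.T @ (xi - _pair_prob(ph, om)) / N_ab

    resid = score(phi) - target
    norm = np.max(np.abs(resid))
    for it in range(1, max_iter + 1):
        if norm <= tol:
            return phi, True, norm
        p = _pair_prob(phi, om)
        w = np.clip(p * (1 - p), 1e-12, None)
        J = (om * w[:, None]).T @ om / N_ab  # dU/dphi (positive definite)
        try:
            step = np.linalg.solve(J, -resid)
        except np.linalg.LinAlgError:
            return phi, False, norm
        mstep = np.max(np.abs(step))
        scale = min(1.0, 5.0 / mstep) if mstep > 0 else 1.0
        for _ in range(30):
            cand = phi + scale * step
            cres = score(cand) - target
            cnorm = np.max(np.abs(cres))
            if cnorm < norm:
                break
            scale *= 0.5
        else:
            return phi, False, norm
        phi, resid, norm = cand, cres, cnorm
    return phi, norm <= tol, norm


def var_Uab(d: PatternDataset, phi_ab, key: str,
            designs: PatternDesigns) -> np.ndarray:
    """(1/N_ab^2) sum over the pair of (xi - p)^2 omega omega'."""
    sel = _pair_mask(d, key)
    N_ab = int((d.category == CATEGORY_OF[key]).sum())
    om = designs.omega[key][sel]
    xi = (d.category[sel] == 0).astype(float)
    res = xi - _pair_prob(phi_ab, om)
    V = (om * res[:, None] ** 2).T @ om / N_ab**2
    return 0.5 * (V + V.T)


@dataclass
class MultiSigma:
    var_U1m: np.ndarray
    var_U2m: np.ndarray     # (q_total, q_total) with cross-pattern blocks
    cov_U1m_U2m: np.ndarray  # (p, q_total)
    sigma_cm: np.ndarray
    n_floored: int

    @property
    def joint(self) -> np.ndarray:
        top = np.hstack([self.var_U1m, self.cov_U1m_U2m])
        bot = np.hstack([self.cov_U1m_U2m.T, self.var_U2m])
        return np.vstack([top, bot])


def sigma_m(d: PatternDataset, beta, phis: dict, designs: PatternDesigns,
            engine: CoxEngine | None = None, include_cross: bool = True,
            prop: MultiPropensity | None = None) -> MultiSigma:
    """Assemble the block covariance of (U1m, U10, U01, U00).

    Cross-pattern blocks arise from the shared fully observed subjects in
    overlapping comparison pairs; ``include_cross=False`` zeroes them for
    sensitivity checks.  Cov(U1m, U_ab) uses per-subject cross products of
    the xi/pi11-weighted integrated score residuals with the U_ab score
    contributions.
    """
    engine = engine or CoxEngine(d)
    prop = prop or propensities(d, phis, designs)
    pi11 = prop.pi11
    xi = (d.category == 0).astype(float)
    w = np.where(xi == 1, 1.0 / np.clip(pi11, 1e-300, None), 0.0)
    resid = engine.integrated_score_residuals(np.asarray(beta, float), w)
    v1 = var_U1(d, resid, np.where(xi == 1, pi11, 1.0))

    keys = active_patterns(d, phis)
    sl, qt = _active_slices(designs, keys)
    V2 = np.zeros((qt, qt))
    C12 = np.zeros((d.p, qt))
    counts = {k: int((d.category == CATEGORY_OF[k]).sum()) for k in keys}
    scores_per_subject = {}
    for k in keys:
        sel = _pair_mask(d, k)
        om = designs.omega[k]
        p = np.zeros(d.n)
        p[sel] = _pair_prob(phis[k], om[sel])
        contrib = np.zeros((d.n, designs.q(k)))
        contrib[sel] = ((d.category[sel] == 0).astype(float) - p[sel])[:, None] \
            * om[sel]
        scores_per_subject[k] = contrib  # per-subject U_ab terms (unnormalised)
        V2[sl[k], sl[k]] = (contrib.T @ contrib) / counts[k] ** 2
        C12[:, sl[k]] = (resid * w[:, None]).T @ contrib / (d.n * counts[k])
    if include_cross:
        for i, ki in enumerate(keys):
            for kj in keys[i + 1:]:
                both = _pair_mask(d, ki) & _pair_mask(d, kj)  # category 11
                A = scores_per_subject[ki][both]
                Bm = scores_per_subject[kj][both]
                blk = A.T @ Bm / (counts[ki] * counts[kj])
                V2[sl[ki], sl[kj]] = blk
                V2[sl[kj], sl[ki]] = blk.T
    if qt == 0:
        return MultiSigma(var_U1m=v1, var_U2m=V2, cov_U1m_U2m=C12,
                          sigma_cm=_floor_psd(v1)[0], n_floored=0)
    try:
        sol = np.linalg.solve(V2, C12.T)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(V2) @ C12.T
    S, n_floored = _floor_psd(v1 - C12 @ sol)
    return MultiSigma(var_U1m=v1, var_U2m=V2, cov_U1m_U2m=C12, sigma_cm=S,
                      n_floored=n_floored)


def sandwich_variance_multi(d: PatternDataset, beta, phis: dict,
                            designs: PatternDesigns,
                            sigma: MultiSigma | None = None,
                            engine: CoxEngine | None = None):
    """Sandwich Var(beta-hat_m, phi-hat) = B^{-1} Sigma_m B^{-T}.

    Bread blocks: dU1m/dbeta = -(weighted information); dU1m/dphi_ab via
    d(1/pi11)/dphi_ab = r_ab omega_ab; dU_ab/dphi_ab = (1/N_ab) sum
    p(1-p) omega omega' (block diagonal across patterns).
    """
    engine = engine or CoxEngine(d)
    beta = np.asarray(beta, dtype=float)
    prop = propensities(d, phis, designs)
    if sigma is None:
        sigma = sigma_m(d, beta, phis, designs, engine=engine, prop=prop)
    xi = (d.category == 0).astype(float)
    pi11 = prop.pi11
    w = np.where(xi == 1, 1.0 / np.clip(pi11, 1e-300, None), 0.0)
    _, info = engine.score_and_information(beta, w)
    p = d.p
    keys = active_patterns(d, phis)
    sl, qt = _active_slices(designs, keys)
    B = np.zeros((p + qt, p + qt))
    B[:p, :p] = -info
    for k in keys:
        om = designs.omega[k]
        r_ab = np.where(xi == 1,
                        prop.pi[:, CATEGORY_OF[k]] / np.clip(pi11, 1e-300, None),
                        0.0)
        gw = (xi * r_ab)[:, None] * np.nan_to_num(om)
        B[:p, p + sl[k].start: p + sl[k].stop] = engine.dscore_dweights(beta, w, gw)
        sel = _pair_mask(d, k)
        N_ab = int((d.category == CATEGORY_OF[k]).sum())
        omp = om[sel]
        pp = _pair_prob(phis[k], omp)
        J = (omp * (pp * (1 - pp))[:, None]).T @ omp / N_ab
        B[p + sl[k].start: p + sl[k].stop, p + sl[k].start: p + sl[k].stop] = J
    Bi = np.linalg.inv(B)
    V = Bi @ sigma.joint @ Bi.T
    return 0.5 * (V + V.T), B


def draw_posterior_multi(d: PatternDataset, designs: PatternDesigns,
                         phis_hat: dict, beta_hat, sigma: MultiSigma,
                         n_draws: int = 1000, seed: int | None = None,
                         engine: CoxEngine | None = None):
    """Approximate-Bayesian draws for the multiple-pattern model.

    Per draw: eta2m* ~ N(0, Var(U2m)) jointly over the three pattern blocks,
    each U_ab solved at its target sub-vector; then eta1* ~ N(0, Sigma_cm)
    and U1m solved with weights xi/pi11*.  Returns (draws_phi, draws_beta,
    n_rejected); draws_phi is (n_draws, q_total) in block order 10, 01, 00.
    """
    from .sampler import _chol_factor
    if seed is None:
        raise ValueError("a seed is required for reproducible posterior draws")
    engine = engine or CoxEngine(d)
    xi = (d.category == 0).astype(float)
    keys = active_patterns(d, phis_hat)
    sl, qt = _active_slices(designs, keys)
    p = d.p
    L2 = _chol_factor(sigma.var_U2m)
    Lc = _chol_factor(sigma.sigma_cm)
    draws_phi = np.empty((n_draws, qt))
    draws_beta = np.empty((n_draws, p))
    n_rejected = 0
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(n_draws)
    beta_hat = np.asarray(beta_hat, float)
    for i in range(n_draws):
        rng = np.random.default_rng(children[i])
        for attempt in range(40):
            eta2 = L2 @ rng.standard_normal(qt) if qt else np.empty(0)
            phis_star = {k: None for k in PATTERN_KEYS}
            ok = True
            for k in keys:
                ph, conv, _ = solve_Uab(d, k, designs, target=eta2[sl[k]],
                                        init=phis_hat[k])
                if not conv:
                    ok = False
                    break
                phis_star[k] = ph
            if not ok:
                n_rejected += 1
                continue
            pi11 = propensities(d, phis_star, designs).pi11
            w = np.where(xi == 1, 1.0 / np.clip(pi11, 1e-300, None), 0.0)
            eta1 = Lc @ rng.standard_normal(p)
            sol = engine.solve(w, target=eta1, init=beta_hat)
            if not sol.converged:
                n_rejected += 1
                continue
            draws_phi[i] = (np.concatenate([phis_star[k] for k in keys])
                            if keys else np.empty(0))
            draws_beta[i] = sol.beta
            break
        else:
            raise RuntimeError("posterior draw failed 40 consecutive times")
        if n_rejected > 0.05 * max(n_draws, i + 1) + 10:
            raise RuntimeError(
                "multi-pattern posterior sampler failure rate exceeded 5%")
    return draws_phi, draws_beta, n_rejected
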