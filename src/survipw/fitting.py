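"""High-level fitting routines shared by the estimator classes, the CLI and
the Monte-Carlo harness.

Each routine takes a :class:`~survipw.data.SurvivalDataset` (or
:class:`~survipw.data.PatternDataset`) and returns a small result object
with point estimates, standard errors and whatever intermediate structure
downstream consumers (sampler, variance checks) need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import multipattern as mp
from .cox import CoxEngine
from .data import PatternDataset, SurvivalDataset, complete_cases
from .propensity import fit_propensity
from .sampler import PosteriorDraws, draw_posterior
from .variance import SandwichVariance, SigmaBlocks, sandwich_variance, sigma_blocks

__all__ = ["CoxFit", "IPWFit", "ABayesFit", "MultiFit", "fit_cc", "fit_ipw",
           "fit_abayes", "fit_multi_ipw", "fit_multi_abayes"]


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    covariance: np.ndarray
    n_iter: int
    converged: bool
    n_used: int


@dataclass
class IPWFit(CoxFit):
    phi: np.ndarray = None
    pi: np.ndarray = None
    min_pi: float = None
    blocks: SigmaBlocks = None
    sandwich: SandwichVariance = None
    design: object = None
    engine: CoxEngine = None
    dataset: SurvivalDataset = None


@dataclass
class ABayesFit(IPWFit):
    draws: PosteriorDraws = None
    posterior_median: np.ndarray = None
    posterior_sd: np.ndarray = None


@dataclass
class MultiFit(CoxFit):
    phis: dict = field(default_factory=dict)
    pi11: np.ndarray = None
    sigma: mp.MultiSigma = None
    designs: mp.PatternDesigns = None
    engine: CoxEngine = None
    draws_beta: np.ndarray = None
    draws_phi: np.ndarray = None
    posterior_median: np.ndarray = None
    posterior_sd: np.ndarray = None


def fit_cc(d: SurvivalDataset, init=None) -> CoxFit:
    """Complete-case stratified Cox fit with model-based variance."""
    cc = complete_cases(d)
    cc.check_events_per_stratum()
    engine = CoxEngine(cc)
    sol = engine.solve(np.ones(cc.n), target=None, init=init)
    if not sol.converged:
        raise RuntimeError(f"complete-case fit did not converge "
                           f"(score norm {sol.score_norm:.2e})")
    cov = np.linalg.inv(sol.information * cc.n)
    return CoxFit(beta=sol.beta, se=np.sqrt(np.diag(cov)), covariance=cov,
                  n_iter=sol.n_iter, converged=True, n_used=cc.n)


def fit_ipw(d: SurvivalDataset, terms=None, floor: float = 0.0,
            init=None, compute_blocks: bool = True) -> IPWFit:
    """IPW point fit with sandwich variance accounting for estimated pi."""
    d.check_events_per_stratum()
    pfit, design = fit_propensity(d, terms=terms, floor=floor)
    xi = d.xi
    w = np.where(xi == 1, 1.0 / np.clip(pfit.pi, 1e-300, None), 0.0)
    engine = CoxEngine(d)
    sol = engine.solve(w, target=None, init=init)
    if not sol.converged:
        raise RuntimeError(f"IPW fit did not converge "
                           f"(score norm {sol.score_norm:.2e})")
    blocks = sand = cov = se = None
    if compute_blocks:
        blocks = sigma_blocks(d, sol.beta, pfit.phi, pfit.pi, design,
                              engine=engine)
        sand = sandwich_variance(d, sol.beta, pfit.phi, pfit.pi, design,
                                 blocks=blocks, engine=engine)
        cov = sand.beta_covariance
        se = sand.beta_se
    return IPWFit(beta=sol.beta, se=se, covariance=cov, n_iter=sol.n_iter,
                  converged=True, n_used=int(xi.sum()), phi=pfit.phi,
                  pi=pfit.pi, min_pi=float(pfit.pi[xi == 1].min()),
                  blocks=blocks, sandwich=sand, design=design, engine=engine,
                  dataset=d)


def fit_abayes(d: SurvivalDataset, terms=None, floor: float = 0.0,
               n_draws: int = 1000, seed: int | None = None,
               fresh_sigma: bool = False) -> ABayesFit:
    """IPW point fit plus calibrated approximate-Bayesian posterior draws."""
    base = fit_ipw(d, terms=terms, floor=floor)
    draws = draw_posterior(d, base.design, base.phi, base.beta, base.blocks,
                           n_draws=n_draws, seed=seed, engine=base.engine,
                           fresh_sigma=fresh_sigma)
    med = np.median(draws.beta, axis=0)
    sd = np.std(draws.beta, axis=0, ddof=1)
    return ABayesFit(**{k: getattr(base, k) for k in (
        "beta", "se", "covariance", "n_iter", "converged", "n_used", "phi",
        "pi", "min_pi", "blocks", "sandwich", "design", "engine", "dataset")},
        draws=draws, posterior_median=med, posterior_sd=sd)


def fit_multi_ipw(d: PatternDataset, terms10=None, terms01=None, terms00=None,
                  init=None) -> MultiFit:
    """Multiple-pattern IPW fit: three conditional-logistic blocks, then the
    weighted Cox score with weights xi/pi11, then the block sandwich."""
    d.check_events_per_stratum()
    designs = mp.build_pattern_designs(d, terms10=terms10, terms01=terms01,
                                       terms00=terms00)
    phis = {}
    for key in mp.PATTERN_KEYS:
        if not (d.category == mp.CATEGORY_OF[key]).any():
            phis[key] = None  # empty pattern: ratio identically zero
            continue
        ph, conv, norm = mp.solve_Uab(d, key, designs, target=None)
        if not conv:
            raise RuntimeError(f"pattern-{key} logistic fit did not converge "
                               f"(score norm {norm:.2e})")
        phis[key] = ph
    prop = mp.propensities(d, phis, designs)
    xi = (d.category == 0).astype(float)
    w = np.where(xi == 1, 1.0 / np.clip(prop.pi11, 1e-300, None), 0.0)
    engine = CoxEngine(d)
    sol = engine.solve(w, target=None, init=init)
    if not sol.converged:
        raise RuntimeError(f"multi-pattern IPW fit did not converge "
                           f"(score norm {sol.score_norm:.2e})")
    sigma = mp.sigma_m(d, sol.beta, phis, designs, engine=engine, prop=prop)
    V, _ = mp.sandwich_variance_multi(d, sol.beta, phis, designs, sigma=sigma,
                                      engine=engine)
    cov = V[: d.p, : d.p]
    return MultiFit(beta=sol.beta, se=np.sqrt(np.diag(cov)), covariance=cov,
                    n_iter=sol.n_iter, converged=True, n_used=int(xi.sum()),
                    phis=phis, pi11=prop.pi11, sigma=sigma, designs=designs,
                    engine=engine)


def fit_multi_abayes(d: PatternDataset, terms10=None, terms01=None,
                     terms00=None, n_draws: int = 1000,
                     seed: int | None = None) -> MultiFit:
    """Multiple-pattern fit plus approximate-Bayesian posterior draws."""
    base = fit_multi_ipw(d, terms10=terms10, terms01=terms01, terms00=terms00)
    dphi, dbeta, _ = mp.draw_posterior_multi(
        d, base.designs, base.phis, base.beta, base.sigma,
        n_draws=n_draws, seed=seed, engine=base.engine)
    base.draws_phi, base.draws_beta = dphi, dbeta
    base.posterior_median = np.median(dbeta, axis=0)
    base.posterior_sd = np.std(dbeta, axis=0, ddof=1)
    return base
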