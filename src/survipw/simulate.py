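"""Synthetic-data generators and the Monte-Carlo evaluation harness.

Two stratified study designs are implemented, each with two strata of equal
size and covariate effects shared across strata.

Design 1 (single missingness pattern)
    Stratum 1: Z1 ~ Bernoulli(0.4), Z2 ~ N(0, 1), baseline cumulative
    hazard Lambda_01(t) = t^4 (Weibull shape 4).  Stratum 2: Z1 ~
    Bernoulli(0.6), Z2 ~ N(1, 0.7^2), Lambda_02(t) = 2 t^{1/3} (Weibull
    shape 1/3).  True effects beta = (log 2, log 2).  Z1 is
    missingness-prone: xi ~ Bernoulli(expit(1.2 - 1.5 I(l=2) + 0.5 Z2 -
    Delta)).  Censoring is Uniform(0, c_l) with c_l calibrated per stratum
    to a common target event fraction (the two baseline hazards live on
    very different time scales, so a shared bound would degenerate one
    stratum).

Design 2 (two missingness-prone covariates)
    Z1 ~ Bernoulli(0.4 / 0.6), Z2 ~ Bernoulli(0.5 / 0.4) by stratum,
    Z3 ~ Uniform(0, 1); constant baseline hazards 1 and 2; beta in
    {(0.3, 0.3, -0.3), (0.7, 0.7, -0.7)}.  The observation category is
    multinomial with ratios r_ab = exp(phi_ab' omega_ab) relative to the
    fully observed category, phi_10 = (-3, 2, 3, -2, -2) on (1, Delta, Z1,
    Z3, I(l=2)), phi_01 = (-1.2, -2, 2, -0.2, 0.1) on (1, Delta, Z2, Z3,
    I(l=2)), phi_00 = (0.3, -1.5, -0.9, 0.1) on (1, Delta, Z3, I(l=2)).
    Censoring is Uniform(0, c) with one bound calibrated to the overall
    event fraction (55% by default).

Event times are drawn by closed-form inversion of the cumulative hazard;
censoring bounds are calibrated by root-finding on a fixed probe sample of
event times, using the exact conditional censoring probability
P(T <= C | T) = max(0, 1 - T/c) so the calibration curve is smooth and
monotone in c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import fitting
from .data import PatternDataset, SurvivalDataset

__all__ = ["Design1", "Design2", "gen_design1", "gen_design2",
           "calibrate_censoring", "run_monte_carlo", "MonteCarloResult",
           "summarize_table"]

CALIBRATION_SEED = 202109
CALIBRATION_N = 100_000


@dataclass
class Design1:
    """Configuration of the single-pattern simulation design."""

    n: int = 1000
    event_rate: float = 0.5          # common per-stratum target
    beta: tuple = (np.log(2), np.log(2))
    phi: tuple = (1.2, -1.5, 0.5, -1.0)   # on (1, I(l=2), Z2, Delta)
    bernoulli_p: tuple = (0.4, 0.6)
    normal_mean: tuple = (0.0, 1.0)
    normal_sd: tuple = (1.0, 0.7)
    censor_bounds: tuple = None      # (c1, c2); None -> calibrate

    # propensity-model terms matching the generating mechanism
    fit_terms = ("z2", "event")

    def inverse_cumhaz(self, stratum: int, e: np.ndarray) -> np.ndarray:
        """Lambda_0l^{-1}: stratum 1 has Lambda = t^4, stratum 2 has 2 t^{1/3}."""
        if stratum == 1:
            return e ** 0.25
        return (e / 2.0) ** 3


@dataclass
class Design2:
    """Configuration of the multiple-pattern simulation design."""

    n: int = 1000
    event_rate: float = 0.55         # overall target, common censoring bound
    beta: tuple = (0.3, 0.3, -0.3)
    phi10: tuple = (-3.0, 2.0, 3.0, -2.0, -2.0)   # (1, Delta, Z1, Z3, I(l=2))
    phi01: tuple = (-1.2, -2.0, 2.0, -0.2, 0.1)   # (1, Delta, Z2, Z3, I(l=2))
    phi00: tuple = (0.3, -1.5, -0.9, 0.1)         # (1, Delta, Z3, I(l=2))
    p_z1: tuple = (0.4, 0.6)
    p_z2: tuple = (0.5, 0.4)
    baseline: tuple = (1.0, 2.0)
    censor_bound: float = None

    fit_terms10 = ("event", "z1", "z3")
    fit_terms01 = ("event", "z2", "z3")
    fit_terms00 = ("event", "z3")
    fit_terms_single = ("event", "time", "z3")


_calibration_cache: dict = {}


def _design1_event_times(cfg: Design1, stratum: int, rng, size: int):
    p = cfg.bernoulli_p[stratum - 1]
    z1 = rng.binomial(1, p, size).astype(float)
    z2 = rng.normal(cfg.normal_mean[stratum - 1], cfg.normal_sd[stratum - 1], size)
    lp = cfg.beta[0] * z1 + cfg.beta[1] * z2
    T = cfg.inverse_cumhaz(stratum, rng.exponential(1.0, size) * np.exp(-lp))
    return T, z1, z2


def _design2_event_times(cfg: Design2, rng, size: int):
    half = size // 2
    strat = np.repeat([0, 1], half)
    z1 = np.concatenate([rng.binomial(1, cfg.p_z1[0], half),
                         rng.binomial(1, cfg.p_z1[1], half)]).astype(float)
    z2 = np.concatenate([rng.binomial(1, cfg.p_z2[0], half),
                         rng.binomial(1, cfg.p_z2[1], half)]).astype(float)
    z3 = rng.uniform(0, 1, 2 * half)
    lam = np.where(strat == 0, cfg.baseline[0], cfg.baseline[1])
    lp = cfg.beta[0] * z1 + cfg.beta[1] * z2 + cfg.beta[2] * z3
    T = rng.exponential(1.0, 2 * half) / (lam * np.exp(lp))
    return T, strat, z1, z2, z3


def _event_fraction(T: np.ndarray, c: float) -> float:
    """P(T <= C) for C ~ Uniform(0, c), exact given the T sample."""
    if not np.isfinite(c):
        return 1.0
    return float(np.mean(np.clip(1.0 - T / c, 0.0, 1.0)))


def _calibrate(T: np.ndarray, target: float, precision: float) -> float:
    """Monotone root-find for the censoring bound achieving the target."""
    if target >= 1.0:
        return np.inf
    lo, hi = 1.0, 1.0
    for _ in range(60):
        if _event_fraction(T, lo) <= target:
            break
        lo /= 2.0
    else:
        raise RuntimeError("censoring calibration: lower bracket not found")
    for _ in range(60):
        if _event_fraction(T, hi) >= target:
            break
        hi *= 2.0
    else:
        raise RuntimeError("censoring calibration: upper bracket not found")
    c = brentq(lambda x: _event_fraction(T, x) - target, lo, hi, xtol=1e-10,
               rtol=1e-12)
    if abs(_event_fraction(T, c) - target) > precision:
        raise RuntimeError("censoring calibration did not reach the target")
    return float(c)


def calibrate_censoring(cfg, target: float | None = None,
                        precision: float = 0.005):
    """Censoring bound(s) achieving the configured event fraction.

    Design 1: per-stratum bounds (c1, c2), each hitting the common target.
    Design 2: a single bound for the pooled sample.  Results are cached by
    (design, beta, target); the probe sample of event times uses a fixed
    calibration seed so bounds are reproducible.
    """
    if isinstance(cfg, Design1):
        target = cfg.event_rate if target is None else target
        key = ("d1", tuple(np.round(cfg.beta, 12)), round(target, 6))
        if key not in _calibration_cache:
            rng = np.random.default_rng(CALIBRATION_SEED)
            bounds = []
            for l in (1, 2):
                T, _, _ = _design1_event_times(cfg, l, rng, CALIBRATION_N)
                bounds.append(_calibrate(T, target, precision))
            _calibration_cache[key] = tuple(bounds)
        return _calibration_cache[key]
    if isinstance(cfg, Design2):
        target = cfg.event_rate if target is None else target
        key = ("d2", tuple(np.round(cfg.beta, 12)), round(target, 6))
        if key not in _calibration_cache:
            rng = np.random.default_rng(CALIBRATION_SEED)
            T, *_ = _design2_event_times(cfg, rng, CALIBRATION_N)
            _calibration_cache[key] = _calibrate(T, target, precision)
        return _calibration_cache[key]
    raise TypeError("cfg must be Design1 or Design2")


def gen_design1(cfg: Design1, seed) -> SurvivalDataset:
    """Generate one design-1 dataset (n even; n/2 subjects per stratum)."""
    if cfg.n % 2:
        raise ValueError("design 1 uses an equal stratum split; n must be even")
    bounds = cfg.censor_bounds or calibrate_censoring(cfg)
    rng = np.random.default_rng(seed)
    half = cfg.n // 2
    parts = []
    for l in (1, 2):
        T, z1, z2 = _design1_event_times(cfg, l, rng, half)
        c = bounds[l - 1]
        C = rng.uniform(0, c, half) if np.isfinite(c) else np.full(half, np.inf)
        X = np.minimum(T, C)
        delta = (T <= C).astype(int)
        f0, f1, f2, f3 = cfg.phi
        pi = expit(f0 + f1 * (l == 2) + f2 * z2 + f3 * delta)
        xi = rng.binomial(1, pi)
        parts.append((X, delta, np.full(half, l), z1, z2, xi))
    X, delta, strat, z1, z2, xi = (np.concatenate([p[i] for p in parts])
                                   for i in range(6))
    mask = np.column_stack([xi.astype(bool), np.ones(cfg.n, dtype=bool)])
    Z = np.column_stack([np.where(xi == 1, z1, np.nan), z2])
    return SurvivalDataset(time=X, event=delta, stratum=strat - 1, Z=Z,
                           mask=mask, covariate_names=["z1", "z2"],
                           stratum_labels=[1, 2])


def gen_design2(cfg: Design2, seed) -> PatternDataset:
    """Generate one design-2 dataset with multinomial observation patterns."""
    if cfg.n % 2:
        raise ValueError("design 2 uses an equal stratum split; n must be even")
    c = cfg.censor_bound or calibrate_censoring(cfg)
    rng = np.random.default_rng(seed)
    T, strat, z1, z2, z3 = _design2_event_times(cfg, rng, cfg.n)
    C = rng.uniform(0, c, cfg.n) if np.isfinite(c) else np.full(cfg.n, np.inf)
    X = np.minimum(T, C)
    delta = (T <= C).astype(int)
    i2 = strat.astype(float)
    r10 = np.exp(np.column_stack([np.ones(cfg.n), delta, z1, z3, i2])
                 @ np.asarray(cfg.phi10))
    r01 = np.exp(np.column_stack([np.ones(cfg.n), delta, z2, z3, i2])
                 @ np.asarray(cfg.phi01))
    r00 = np.exp(np.column_stack([np.ones(cfg.n), delta, z3, i2])
                 @ np.asarray(cfg.phi00))
    den = 1.0 + r10 + r01 + r00
    P = np.column_stack([1.0 / den, r10 / den, r01 / den, r00 / den])
    u = rng.random(cfg.n)
    cum = np.cumsum(P, axis=1)
    cat = (u[:, None] > cum[:, :3]).sum(axis=1)  # 0=11, 1=10, 2=01, 3=00
    eta1 = np.isin(cat, (0, 1))
    eta2 = np.isin(cat, (0, 2))
    Z = np.column_stack([np.where(eta1, z1, np.nan),
                         np.where(eta2, z2, np.nan), z3])
    mask = np.column_stack([eta1, eta2, np.ones(cfg.n, dtype=bool)])
    return PatternDataset(time=X, event=delta, stratum=strat, Z=Z, mask=mask,
                          covariate_names=["z1", "z2", "z3"],
                          stratum_labels=[1, 2], missing_idx=(0, 1))


# ---------------------------------------------------------------------------
# Monte-Carlo harness

DESIGN1_METHODS = ("abayes", "ipw", "cc")
DESIGN2_METHODS = ("mm-abayes", "mm-ipw", "sm-abayes", "sm-ipw", "cc")


@dataclass
class MonteCarloResult:
    """Per-method point estimates and interval indicators over replicates."""

    truth: np.ndarray
    param_names: list
    methods: list
    estimates: dict            # method -> (B_ok, p)
    spread: dict               # method -> (B_ok, p) SEs / posterior SDs
    covered: dict              # method -> (B_ok, p) bool, 95% CI or ETI
    n_failed: int
    B: int
    meta: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for m in self.methods:
            est = self.estimates[m]
            bias = est.mean(axis=0) - self.truth
            sd = est.std(axis=0, ddof=1) if est.shape[0] > 1 else \
                np.full(est.shape[1], np.nan)
            se = self.spread[m].mean(axis=0)
            cr = self.covered[m].mean(axis=0)
            for j, name in enumerate(self.param_names):
                rows.append({"method": m, "param": name,
                             "truth": self.truth[j], "bias": bias[j],
                             "SD": sd[j], "SE": se[j], "CR": cr[j],
                             "B": est.shape[0]})
        return pd.DataFrame(rows)


def _fit_one_design1(d, method, cfg: Design1, n_draws, seed):
    z = 1.959963984540054
    if method == "cc":
        r = fitting.fit_cc(d)
        return r.beta, r.se, (np.abs(r.beta - np.asarray(cfg.beta)) <= z * r.se)
    if method == "ipw":
        r = fitting.fit_ipw(d, terms=list(cfg.fit_terms))
        return r.beta, r.se, (np.abs(r.beta - np.asarray(cfg.beta)) <= z * r.se)
    if method == "abayes":
        r = fitting.fit_abayes(d, terms=list(cfg.fit_terms), n_draws=n_draws,
                               seed=seed)
        lo = np.quantile(r.draws.beta, 0.025, axis=0)
        hi = np.quantile(r.draws.beta, 0.975, axis=0)
        truth = np.asarray(cfg.beta)
        return r.posterior_median, r.posterior_sd, (lo <= truth) & (truth <= hi)
    raise ValueError(f"unknown design-1 method {method!r}")


def _fit_one_design2(d, method, cfg: Design2, n_draws, seed):
    z = 1.959963984540054
    truth = np.asarray(cfg.beta)
    if method == "cc":
        r = fitting.fit_cc(d)
        return r.beta, r.se, (np.abs(r.beta - truth) <= z * r.se)
    if method == "mm-ipw":
        r = fitting.fit_multi_ipw(d, terms10=list(cfg.fit_terms10),
                                  terms01=list(cfg.fit_terms01),
                                  terms00=list(cfg.fit_terms00))
        return r.beta, r.se, (np.abs(r.beta - truth) <= z * r.se)
    if method == "mm-abayes":
        r = fitting.fit_multi_abayes(d, terms10=list(cfg.fit_terms10),
                                     terms01=list(cfg.fit_terms01),
                                     terms00=list(cfg.fit_terms00),
                                     n_draws=n_draws, seed=seed)
        lo = np.quantile(r.draws_beta, 0.025, axis=0)
        hi = np.quantile(r.draws_beta, 0.975, axis=0)
        return r.posterior_median, r.posterior_sd, (lo <= truth) & (truth <= hi)
    if method == "sm-ipw":
        r = fitting.fit_ipw(d, terms=list(cfg.fit_terms_single))
        return r.beta, r.se, (np.abs(r.beta - truth) <= z * r.se)
    if method == "sm-abayes":
        r = fitting.fit_abayes(d, terms=list(cfg.fit_terms_single),
                               n_draws=n_draws, seed=seed)
        lo = np.quantile(r.draws.beta, 0.025, axis=0)
        hi = np.quantile(r.draws.beta, 0.975, axis=0)
        return r.posterior_median, r.posterior_sd, (lo <= truth) & (truth <= hi)
    raise ValueError(f"unknown design-2 method {method!r}")


def run_monte_carlo(cfg, methods, B: int, n_draws: int = 1000,
                    seed: int | None = None,
                    fail_limit: float = 0.02) -> MonteCarloResult:
    """Replicate the design B times and fit every requested method.

    Per-replicate seeds are independent child streams of the master seed.
    Replicates where any solver fails are dropped (all methods at once, to
    keep the method comparison paired); more than ``fail_limit`` failures
    aborts.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if seed is None:
        raise ValueError("run_monte_carlo requires a seed")
    is_d1 = isinstance(cfg, Design1)
    known = DESIGN1_METHODS if is_d1 else DESIGN2_METHODS
    for m in methods:
        if m not in known:
            raise ValueError(f"unknown method {m!r} for this design")
    calibrate_censoring(cfg)  # warm the cache before replicating
    truth = np.asarray(cfg.beta, dtype=float)
    p = len(truth)
    est = {m: [] for m in methods}
    spread = {m: [] for m in methods}
    cover = {m: [] for m in methods}
    n_failed = 0
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    for b in range(B):
        data_seed, draw_seed = children[b].spawn(2)
        d = gen_design1(cfg, data_seed) if is_d1 else gen_design2(cfg, data_seed)
        try:
            results = {}
            for m in methods:
                if is_d1:
                    results[m] = _fit_one_design1(d, m, cfg, n_draws, draw_seed)
                else:
                    results[m] = _fit_one_design2(d, m, cfg, n_draws, draw_seed)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            if n_failed > max(fail_limit * B, 2):
                raise RuntimeError(
                    f"{n_failed} of {b + 1} Monte-Carlo replicates failed; "
                    "aborting (check the design configuration)")
            continue
        for m in methods:
            e, s, c = results[m]
            est[m].append(e)
            spread[m].append(s)
            cover[m].append(c)
    names = [f"z{j + 1}" for j in range(p)]
    return MonteCarloResult(
        truth=truth, param_names=names, methods=list(methods),
        estimates={m: np.asarray(v) for m, v in est.items()},
        spread={m: np.asarray(v) for m, v in spread.items()},
        covered={m: np.asarray(v, dtype=bool) for m, v in cover.items()},
        n_failed=n_failed, B=B,
        meta={"design": 1 if is_d1 else 2, "n": cfg.n,
              "event_rate": cfg.event_rate, "seed": seed, "n_draws": n_draws})


def summarize_table(results) -> pd.DataFrame:
    """Stack MonteCarloResult tables into one tidy report frame."""
    frames = []
    for r in np.atleast_1d(results):
        t = r.table()
        for k, v in r.meta.items():
            t[k] = v
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["method", "param", "truth", "bias",
                                     "SD", "SE", "CR", "B"])
    return pd.concat(frames, ignore_index=True)
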