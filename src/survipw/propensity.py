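"""Logistic response-probability model for a single missingness pattern.

Under MAR, the probability that a subject's covariates are fully observed is
modelled as ``pi = expit(phi' omega)`` where ``omega`` contains an intercept,
stratum indicators (stratum code 0 is the reference) and fully observed
subject-level quantities ``W`` (by default the event indicator, the observed
time and every always-observed covariate).

Beyond the ordinary MLE, the module solves the *perturbed* score system
``U2(phi) = eta2*`` for arbitrary finite targets, which the posterior
sampler calls once per draw.  ``U2`` is the Bernoulli score divided by n, so
its Jacobian is minus the Fisher information over n; the system is solved by
damped Newton iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import SurvivalDataset

__all__ = [
    "ResponseDesign",
    "PropensityFit",
    "build_response_design",
    "score_U2",
    "solve_U2",
    "var_U2",
    "fit_propensity",
]

NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 100
NEWTON_MAX_HALVINGS = 30


@dataclass
class ResponseDesign:
    """Per-subject design rows omega (n x q) for the response model."""

    omega: np.ndarray
    column_names: list

    @property
    def q(self) -> int:
        return self.omega.shape[1]

    @property
    def n(self) -> int:
        return self.omega.shape[0]


@dataclass
class PropensityFit:
    """Solution of U2(phi) = target with fitted probabilities."""

    phi: np.ndarray
    pi: np.ndarray
    converged: bool
    n_iter: int
    score_norm: float


def build_response_design(d: SurvivalDataset, terms=None) -> ResponseDesign:
    """Build omega = (1, I(l=2), ..., I(l=L), W) for the response model.

    ``terms`` selects the W columns by name: ``"event"``, ``"time"``, or any
    fully observed covariate name.  Default: event, time, then every fully
    observed covariate.  Missingness-prone covariates are rejected (the MAR
    conditioning set is the observed data only).
    """
    fully_observed = [name for j, name in enumerate(d.covariate_names)
                      if d.mask[:, j].all()]
    if terms is None:
        terms = ["event", "time"] + fully_observed
    cols = [np.ones(d.n)]
    names = ["intercept"]
    for code in range(1, d.n_strata):
        cols.append((d.stratum == code).astype(float))
        names.append(f"stratum[{d.stratum_labels[code]!r}]")
    for t in terms:
        if t == "event":
            cols.append(d.event.astype(float))
        elif t == "time":
            cols.append(d.time)
        elif t in d.covariate_names:
            if t not in fully_observed:
                raise ValueError(
                    f"covariate {t!r} has missing values and cannot enter the "
                    "response model (MAR conditions on observed data only)"
                )
            cols.append(d.Z[:, d.covariate_names.index(t)])
        else:
            raise ValueError(f"unknown response-model term {t!r}")
        names.append(t)
    return ResponseDesign(omega=np.column_stack(cols), column_names=names)


def score_U2(phi: np.ndarray, design: ResponseDesign, xi: np.ndarray) -> np.ndarray:
    """Logistic score (1/n) sum (xi - pi) omega at coefficients phi."""
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite coefficients")
    if phi.shape[0] != design.q:
        raise ValueError(f"phi has length {phi.shape[0]}, design has q={design.q}")
    pi = expit(design.omega @ phi)
    return design.omega.T @ (np.asarray(xi) - pi) / design.n


def var_U2(phi: np.ndarray, design: ResponseDesign) -> np.ndarray:
    """(1/n^2) sum pi(1-pi) omega omega' — the U2 perturbation covariance."""
    pi = expit(design.omega @ np.asarray(phi, dtype=float))
    w = pi * (1.0 - pi)
    V = (design.omega * w[:, None]).T @ design.omega / design.n**2
    return 0.5 * (V + V.T)


def solve_U2(design: ResponseDesign, xi: np.ndarray, target=None,
             init=None, tol: float = NEWTON_TOL,
             max_iter: int = NEWTON_MAX_ITER) -> PropensityFit:
    """Solve U2(phi) = target by damped Newton (target 0 gives the MLE).

    The Jacobian of U2 is -(1/n) X'diag(pi(1-pi))X, so the system is a
    shifted concave-gradient problem; step-halving on the residual norm
    guarantees monotone progress away from separation.
    """
    xi = np.asarray(xi, dtype=float)
    q = design.q
    target = np.zeros(q) if target is None else np.asarray(target, dtype=float)
    if not np.all(np.isfinite(target)):
        raise ValueError("non-finite target for U2")
    phi = np.zeros(q) if init is None else np.asarray(init, dtype=float).copy()

    resid = score_U2(phi, design, xi) - target
    norm = np.max(np.abs(resid))
    for it in range(1, max_iter + 1):
        if norm <= tol:
            return PropensityFit(phi, expit(design.omega @ phi), True, it - 1, norm)
        pi = expit(design.omega @ phi)
        w = np.clip(pi * (1.0 - pi), 1e-12, None)
        info = (design.omega * w[:, None]).T @ design.omega / design.n
        try:
            step = np.linalg.solve(info, resid)
        except np.linalg.LinAlgError:
            return PropensityFit(phi, pi, False, it, norm)
        # cap the raw step so saturated regions cannot catapult the iterate
        mstep = np.max(np.abs(step))
        scale = min(1.0, 5.0 / mstep) if mstep > 0 else 1.0
        for _ in range(NEWTON_MAX_HALVINGS):
            cand = phi + scale * step
            cres = score_U2(cand, design, xi) - target
            cnorm = np.max(np.abs(cres))
            if cnorm < norm:
                break
            scale *= 0.5
        else:
            return PropensityFit(phi, pi, False, it, norm)
        phi, resid, norm = cand, cres, cnorm
    converged = norm <= tol
    return PropensityFit(phi, expit(design.omega @ phi), converged, max_iter, norm)


def fit_propensity(d: SurvivalDataset, terms=None, floor: float = 0.0,
                   tol: float = NEWTON_TOL) -> tuple[PropensityFit, ResponseDesign]:
    """MLE of the response model; optional floor pi >= eps for the weights.

    Returns the fit and the design.  ``floor > 0`` truncates fitted
    probabilities from below (the positivity condition made operational);
    the number of floored subjects is recorded on the fit object.
    """
    design = build_response_design(d, terms=terms)
    fit = solve_U2(design, d.xi, target=None, tol=tol)
    if not fit.converged:
        raise RuntimeError(
            f"propensity MLE did not converge (score norm {fit.score_norm:.2e}); "
            "possible complete separation"
        )
    if floor > 0:
        n_floored = int((fit.pi < floor).sum())
        fit.pi = np.maximum(fit.pi, floor)
        fit.n_floored = n_floored
    return fit, design
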