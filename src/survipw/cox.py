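"""Weighted stratified Cox partial-likelihood machinery.

All estimating functions here are built from the weight-scaled risk-set
moments

    S^(d)_l(beta, t) = (1/n) sum_i w_i Y_li(t) Z_li^{(x)d} exp(beta'Z_li),

with Y(t) = I(X >= t) (a subject is at risk at its own observed time) and
Breslow handling of ties.  Weights are arbitrary nonnegative reals supplied
by the caller — xi/pi for IPW, 1 for the classical estimator — and must be
zero for any subject with unobserved covariates (those rows of Z are not
interpretable).

The module exposes the weighted score ``U1``, its information matrix, the
Breslow baseline increments, the per-subject integrated score residuals

    int_0^tau {Z_li - S^(1)/S^(0)} dM-hat_li(t)

that form the "meat" of every variance block, a Newton solver for the
perturbed system ``U1(beta) = eta1*``, and the derivative of ``U1`` with
respect to parameters entering through the weights (used for the bread of
the sandwich variance).

Everything is evaluated through a per-stratum descending-time sort computed
once per :class:`CoxEngine`; each evaluation is O(n p^2) with vectorised
cumulative sums, cheap enough to be called thousands of times by the
posterior sampler and the Monte-Carlo harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset

__all__ = [
    "CoxEngine",
    "BaselineHazard",
    "CoxSolution",
    "risk_moments",
    "score_U1",
    "breslow",
    "integrated_score_residuals",
    "solve_U1",
]

NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 100
NEWTON_MAX_HALVINGS = 30
BETA_BOUND = 50.0


@dataclass
class BaselineHazard:
    """Per-stratum Breslow increments at the distinct event times."""

    times: list      # per stratum: ascending distinct event times
    increments: list  # per stratum: dLambda-hat at those times

    def cumulative(self, stratum: int):
        return self.times[stratum], np.cumsum(self.increments[stratum])


@dataclass
class CoxSolution:
    beta: np.ndarray
    converged: bool
    n_iter: int
    score_norm: float
    information: np.ndarray  # weighted information at beta (1/n scale)


class CoxEngine:
    """Precomputed sort structure for repeated weighted-score evaluations."""

    def __init__(self, d: SurvivalDataset):
        self.d = d
        self.n = d.n
        self.p = d.p
        # contiguous strata, descending time within stratum
        self.order = np.lexsort((-d.time, d.stratum))
        self.time_s = d.time[self.order]
        self.event_s = d.event[self.order].astype(bool)
        self.strat_s = d.stratum[self.order]
        Z = np.where(d.mask, d.Z, 0.0)  # masked entries must carry zero weight
        self.Z_s = Z[self.order]
        # stratum block boundaries in sorted order
        self.block_start = np.searchsorted(self.strat_s, np.arange(d.n_strata))
        self.block_end = np.searchsorted(self.strat_s, np.arange(d.n_strata), "right")
        # tie_end[i]: last sorted index with the same (stratum, time) as i,
        # so cumulative sums taken at tie_end include the whole risk set at t_i
        same = np.empty(self.n, dtype=bool)
        same[:-1] = (self.time_s[1:] == self.time_s[:-1]) & \
                    (self.strat_s[1:] == self.strat_s[:-1])
        same[-1] = False
        bounds = np.flatnonzero(~same)
        self.tie_end = bounds[np.searchsorted(bounds, np.arange(self.n))]
        self.event_pos = np.flatnonzero(self.event_s)

    # -- internal -----------------------------------------------------------

    def _risk(self, beta, w):
        """exp(beta'Z)*w in sorted order plus per-stratum cumulative sums."""
        ws = w[self.order]
        eta = self.Z_s @ beta
        r = ws * np.exp(eta)
        cum0 = self._block_cumsum(r)
        cum1 = self._block_cumsum(r[:, None] * self.Z_s)
        return ws, r, cum0, cum1

    def _block_cumsum(self, x):
        """Cumulative sum restarted at each stratum block (descending time)."""
        c = np.cumsum(x, axis=0)
        out = c.copy()
        for l in range(1, len(self.block_start)):
            s = self.block_start[l]
            if s < self.n:
                out[s:self.block_end[l]] = (
                    c[s:self.block_end[l]] - c[s - 1]
                )
        return out

    # -- public surface -----------------------------------------------------

    def score(self, beta, w):
        """U1(beta) = (1/n) sum_l sum_i w_i int {Z - S1/S0} dN_i."""
        beta = np.asarray(beta, dtype=float)
        ws, r, cum0, cum1 = self._risk(beta, w)
        ev = self.event_pos[ws[self.event_pos] > 0]
        te = self.tie_end[ev]
        S0 = cum0[te]
        if np.any(S0 <= 0):
            raise ValueError("S^(0) is zero at an event time (empty weighted risk set)")
        Ebar = cum1[te] / S0[:, None]
        contrib = ws[ev, None] * (self.Z_s[ev] - Ebar)
        return contrib.sum(axis=0) / self.n

    def score_and_information(self, beta, w):
        """Score and weighted information (-dU1/dbeta), both on the 1/n scale."""
        beta = np.asarray(beta, dtype=float)
        ws, r, cum0, cum1 = self._risk(beta, w)
        rz2 = r[:, None, None] * (self.Z_s[:, :, None] * self.Z_s[:, None, :])
        cum2 = self._block_cumsum(rz2.reshape(self.n, -1)).reshape(self.n, self.p, self.p)
        ev = self.event_pos[ws[self.event_pos] > 0]
        te = self.tie_end[ev]
        S0 = cum0[te]
        if np.any(S0 <= 0):
            raise ValueError("S^(0) is zero at an event time (empty weighted risk set)")
        Ebar = cum1[te] / S0[:, None]
        V = cum2[te] / S0[:, None, None] - Ebar[:, :, None] * Ebar[:, None, :]
        wev = ws[ev]
        score = (wev[:, None] * (self.Z_s[ev] - Ebar)).sum(axis=0) / self.n
        info = (wev[:, None, None] * V).sum(axis=0) / self.n
        return score, info

    def breslow(self, beta, w, form: str = "ipw") -> BaselineHazard:
        """Breslow baseline-hazard increments per stratum.

        ``form="ipw"`` (default): dLambda(t) = sum_i w_i dN_i(t) /
        sum_i w_i Y_i(t) exp(beta'Z_i) — normalisation-free, and the form
        under which weighted martingale residuals sum to zero per stratum.
        ``form="printed"``: unweighted event count in the numerator over
        n_l S^(0) with S^(0) carrying a 1/n factor.
        """
        beta = np.asarray(beta, dtype=float)
        ws, r, cum0, _ = self._risk(beta, w)
        times, incs = [], []
        wev = self.event_pos[ws[self.event_pos] > 0] if form == "ipw" \
            else self.event_pos
        for l in range(len(self.block_start)):
            s, e = self.block_start[l], self.block_end[l]
            ev = wev[(wev >= s) & (wev < e)]
            if len(ev) == 0:
                times.append(np.empty(0))
                incs.append(np.empty(0))
                continue
            te = self.tie_end[ev]
            t_ev = self.time_s[ev]
            uniq_end, first_idx = np.unique(te, return_index=True)
            ut = t_ev[first_idx]
            denom = cum0[uniq_end]
            if form == "ipw":
                num = np.bincount(te - s, weights=ws[ev], minlength=e - s)[uniq_end - s]
            elif form == "printed":
                nl = e - s
                num = np.bincount(te - s, minlength=e - s)[uniq_end - s].astype(float)
                denom = nl * (denom / self.n)
            else:
                raise ValueError(f"unknown Breslow form {form!r}")
            if np.any(denom <= 0):
                raise ValueError("zero weighted risk set at an event time")
            # ascending time
            times.append(ut[::-1].copy())
            incs.append((num / denom)[::-1].copy())
        return BaselineHazard(times=times, increments=incs)

    def integrated_score_residuals(self, beta, w, form: str = "ipw"):
        """Per-subject int {Z - S1/S0} dM-hat (n x p, original row order).

        Rows for subjects with unobserved covariates use zero-filled Z and
        are meaningless; callers weight them by zero.
        """
        beta = np.asarray(beta, dtype=float)
        ws, r, cum0, cum1 = self._risk(beta, w)
        base = self.breslow(beta, w, form=form)
        eeta = np.exp(self.Z_s @ beta)
        resid_s = np.zeros((self.n, self.p))
        ev_all = self.event_pos[ws[self.event_pos] > 0]
        te_all = self.tie_end[ev_all]
        Ebar_ev = cum1[te_all] / cum0[te_all][:, None]
        resid_s[ev_all] = self.Z_s[ev_all] - Ebar_ev
        for l in range(len(self.block_start)):
            s, e = self.block_start[l], self.block_end[l]
            t_l, dL = base.times[l], base.increments[l]
            if len(t_l) == 0:
                continue
            ev = ev_all[(ev_all >= s) & (ev_all < e)]
            te = self.tie_end[ev]
            uniq_end = np.unique(te)[::-1]  # ascending time
            Ebar_u = cum1[uniq_end] / cum0[uniq_end][:, None]
            A0 = np.cumsum(dL)
            A1 = np.cumsum(Ebar_u * dL[:, None], axis=0)
            idx = np.searchsorted(t_l, self.time_s[s:e], side="right") - 1
            at_risk = idx >= 0
            idxc = np.clip(idx, 0, None)
            drift = eeta[s:e, None] * (
                self.Z_s[s:e] * A0[idxc][:, None] - A1[idxc]
            )
            drift[~at_risk] = 0.0
            resid_s[s:e] -= drift
        out = np.zeros((self.n, self.p))
        out[self.order] = resid_s
        return out

    def solve(self, w, target=None, init=None, tol: float = NEWTON_TOL,
              max_iter: int = NEWTON_MAX_ITER,
              beta_bound: float = BETA_BOUND) -> CoxSolution:
        """Solve U1(beta) = target by damped Newton with step-halving."""
        target = np.zeros(self.p) if target is None else np.asarray(target, float)
        if not np.all(np.isfinite(target)):
            raise ValueError("non-finite target for U1")
        beta = np.zeros(self.p) if init is None else np.asarray(init, float).copy()
        score, info = self.score_and_information(beta, w)
        resid = score - target
        norm = np.max(np.abs(resid))
        for it in range(1, max_iter + 1):
            if norm <= tol:
                return CoxSolution(beta, True, it - 1, norm, info)
            try:
                step = np.linalg.solve(info, resid)
            except np.linalg.LinAlgError:
                return CoxSolution(beta, False, it, norm, info)
            mstep = np.max(np.abs(step))
            scale = min(1.0, 5.0 / mstep) if mstep > 0 else 1.0
            for _ in range(NEWTON_MAX_HALVINGS):
                cand = beta + scale * step
                if np.max(np.abs(cand)) <= beta_bound:
                    try:
                        cscore, cinfo = self.score_and_information(cand, w)
                    except (ValueError, FloatingPointError):
                        scale *= 0.5
                        continue
                    cres = cscore - target
                    cnorm = np.max(np.abs(cres))
                    if np.isfinite(cnorm) and cnorm < norm:
                        break
                scale *= 0.5
            else:
                return CoxSolution(beta, False, it, norm, info)
            beta, resid, norm, info = cand, cres, cnorm, cinfo
        return CoxSolution(beta, norm <= tol, max_iter, norm, info)

    def dscore_dweights(self, beta, w, gw):
        """d U1 / d param for parameters entering only through the weights.

        ``gw`` is (n, q) with gw[i, k] = d w_i / d param_k.  Accounts for
        both the direct w_i term at each event and the dependence of
        S^(1)/S^(0) on the weights.  Returns (p, q).
        """
        beta = np.asarray(beta, dtype=float)
        gw = np.atleast_2d(np.asarray(gw, dtype=float))
        if gw.shape[0] != self.n:
            gw = gw.T
        q = gw.shape[1]
        ws, r, cum0, cum1 = self._risk(beta, w)
        eeta = np.exp(self.Z_s @ beta)
        g_s = gw[self.order]
        gr = g_s * eeta[:, None]                       # (n, q)
        cumg0 = self._block_cumsum(gr)                 # (n, q)
        grz = gr[:, :, None] * self.Z_s[:, None, :]    # (n, q, p)
        cumg1 = self._block_cumsum(grz.reshape(self.n, -1)).reshape(self.n, q, self.p)
        ev = self.event_pos[ws[self.event_pos] > 0]
        te = self.tie_end[ev]
        S0 = cum0[te]
        Ebar = cum1[te] / S0[:, None]                  # (m, p)
        direct = (self.Z_s[ev] - Ebar)[:, :, None] * g_s[ev][:, None, :]  # (m,p,q)
        dS0 = cumg0[te]                                # (m, q)
        dS1 = cumg1[te]                                # (m, q, p)
        dEbar = (dS1 - dS0[:, :, None] * Ebar[:, None, :]) / S0[:, None, None]
        indirect = ws[ev][:, None, None] * np.transpose(dEbar, (0, 2, 1))  # (m,p,q)
        return (direct - indirect).sum(axis=0) / self.n


# ---------------------------------------------------------------------------
# thin functional wrappers over the engine (the documented operation surface)

def risk_moments(d: SurvivalDataset, beta, weights):
    """S^(0), S^(1) per stratum at each distinct event time (ascending).

    Returns a list over strata of ``(times, S0, S1)`` with the printed 1/n
    normalisation.
    """
    eng = CoxEngine(d)
    beta = np.asarray(beta, dtype=float)
    ws, r, cum0, cum1 = eng._risk(beta, np.asarray(weights, float))
    out = []
    for l in range(len(eng.block_start)):
        s, e = eng.block_start[l], eng.block_end[l]
        ev = eng.event_pos[(eng.event_pos >= s) & (eng.event_pos < e)]
        te = np.unique(eng.tie_end[ev])[::-1]
        out.append((eng.time_s[te], cum0[te] / d.n, cum1[te] / d.n))
    return out


def score_U1(d: SurvivalDataset, beta, weights):
    return CoxEngine(d).score(np.asarray(beta, float), np.asarray(weights, float))


def breslow(d: SurvivalDataset, beta, weights, form: str = "ipw") -> BaselineHazard:
    return CoxEngine(d).breslow(np.asarray(beta, float), np.asarray(weights, float),
                                form=form)


def integrated_score_residuals(d: SurvivalDataset, beta, weights, form: str = "ipw"):
    return CoxEngine(d).integrated_score_residuals(
        np.asarray(beta, float), np.asarray(weights, float), form=form)


def solve_U1(d: SurvivalDataset, weights, target=None, init=None, **kw) -> CoxSolution:
    return CoxEngine(d).solve(np.asarray(weights, float), target=target, init=init, **kw)
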