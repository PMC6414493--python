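"""Cox proportional-hazards machinery: partial likelihood, Newton solver,
Schoenfeld residuals and the proportional-hazards score test.

The partial likelihood uses the Efron correction for tied event times
(Breslow available behind a flag).  The solver is plain Newton–Raphson with
step-halving, which keeps the partial log-likelihood non-decreasing across
iterations.  A :class:`SurvData` object pre-sorts the survival times and
groups tied events so that repeated fits on the same cohort (the per-variant
scan) only pay the sorting cost once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SurvData", "CoxFit", "cox_fit", "schoenfeld_residuals", "zph_test"]

_ETA_CAP = 500.0  # exp() overflow guard on the linear predictor


class SurvData:
    """Pre-sorted survival data shared across Cox fits on one cohort.

    Parameters
    ----------
    time : array of float
        Follow-up times (age scale), all > 0.
    event : array of {0,1}
        1 = event observed at ``time``, 0 = right-censored.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be equal-length 1-D arrays")
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("all survival times must be finite and > 0")
        event = event.astype(bool)
        if not event.any():
            raise ValueError("no events in the data; Cox model is undefined")

        self.n = time.size
        self.n_events = int(event.sum())
        # ascending time; within ties events are contiguous among the
        # event-only subsequence, which is all the grouping below needs
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order]

        ev_times = self.time[self.event]
        uniq, first = np.unique(ev_times, return_index=True)
        self.group_times = uniq                       # unique event times, asc
        # position in the sorted arrays where each risk set begins
        self.risk_start = np.searchsorted(self.time, uniq, side="left")
        # slices of the event-only subsequence belonging to each tied group
        counts = np.diff(np.append(first, ev_times.size))
        self.death_counts = counts.astype(int)
        self.death_start = first
        self.event_idx = np.flatnonzero(self.event)   # positions in sorted arrays
        self.max_ties = int(counts.max())

    def sort_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.n:
            raise ValueError("X row count does not match survival data")
        return X[self.order]


def _suffix_sums(sd: SurvData, Xs, eta):
    """Risk-set and tied-death sums entering the Efron likelihood."""
    w = np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))
    wX = w[:, None] * Xs
    wXX = wX[:, :, None] * Xs[:, None, :]

    # suffix cumulative sums evaluated at each risk-set start
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wX[::-1], axis=0)[::-1]
    s2 = np.cumsum(wXX[::-1], axis=0)[::-1]
    S0 = s0[sd.risk_start]
    S1 = s1[sd.risk_start]
    S2 = s2[sd.risk_start]

    # per-group sums over the tied deaths
    ev = sd.event_idx
    D0 = np.add.reduceat(w[ev], sd.death_start)
    D1 = np.add.reduceat(wX[ev], sd.death_start, axis=0)
    D2 = np.add.reduceat(wXX[ev], sd.death_start, axis=0)
    eta_dead = np.add.reduceat(eta[ev], sd.death_start)
    x_dead = np.add.reduceat(Xs[ev], sd.death_start, axis=0)
    return S0, S1, S2, D0, D1, D2, eta_dead, x_dead


def _loglik_grad_hess(beta, sd: SurvData, Xs, ties="efron", want_derivs=True):
    eta = Xs @ beta
    S0, S1, S2, D0, D1, D2, eta_dead, x_dead = _suffix_sums(sd, Xs, eta)
    d = sd.death_counts.astype(float)
    p = Xs.shape[1]

    ll = float(eta_dead.sum())
    grad = x_dead.sum(axis=0) if want_derivs else None
    hess = np.zeros((p, p)) if want_derivs else None

    n_inner = sd.max_ties if ties == "efron" else 1
    for l in range(n_inner):
        live = d > l
        frac = (l / d[live]) if ties == "efron" else 0.0
        S0l = S0[live] - (frac * D0[live] if ties == "efron" else 0.0)
        ll -= float(np.log(S0l).sum())
        if want_derivs:
            S1l = S1[live] - (frac[:, None] * D1[live] if ties == "efron" else 0.0)
            S2l = S2[live] - (frac[:, None, None] * D2[live] if ties == "efron" else 0.0)
            mu = S1l / S0l[:, None]
            grad -= mu.sum(axis=0)
            hess += (S2l / S0l[:, None, None]).sum(axis=0)
            hess -= np.einsum("ij,ik->jk", mu, mu)
    if ties == "breslow":
        # Breslow treats the d tied deaths as d draws from the same risk set
        ll_extra = (d - 1) * np.log(S0)
        ll -= float(ll_extra.sum())
        if want_derivs:
            mu = S1 / S0[:, None]
            grad -= ((d - 1)[:, None] * mu).sum(axis=0)
            hess += ((d - 1)[:, None, None] * S2 / S0[:, None, None]).sum(axis=0)
            hess -= np.einsum("i,ij,ik->jk", d - 1, mu, mu)
    return ll, grad, hess


@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood maximization."""

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    n: int
    n_events: int
    ll_path: np.ndarray

    @property
    def z(self):
        return self.beta / self.se

    @property
    def p(self):
        return 2.0 * stats.norm.sf(np.abs(self.z))


def cox_fit(X, time=None, event=None, *, data: SurvData | None = None,
            ties: str = "efron", tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton's method.

    Either ``data`` (a prebuilt :class:`SurvData`) or ``time``/``event``
    must be given.  Convergence is declared when the partial log-likelihood
    changes by less than ``tol``; step-halving guarantees monotone ascent.

    Raises
    ------
    ValueError
        If a column of X is constant (the coefficient is unidentifiable)
        or no events are present.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    sd = data if data is not None else SurvData(time, event)
    Xs = sd.sort_X(X)
    if np.any(np.nanstd(Xs, axis=0) == 0):
        raise ValueError("constant covariate column in Cox design")
    p = Xs.shape[1]

    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, sd, Xs, ties)
    ll0 = ll
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _loglik_grad_hess(cand, sd, Xs, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:  # could not improve
            break
        delta = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        path.append(ll)
        if abs(delta) < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    if not np.all(np.isfinite(se)) or np.any(np.abs(beta) > 50):
        converged = False
    return CoxFit(beta=beta, se=se, cov=cov, loglik=ll, loglik_null=ll0,
                  n_iter=it, converged=converged, n=sd.n,
                  n_events=sd.n_events, ll_path=np.array(path))


def schoenfeld_residuals(fit: CoxFit, sd: SurvData, X):
    """Efron-weighted Schoenfeld residuals, one row per event (time order).

    For a tied group of size d the l-th death (l = 0..d-1) is compared with
    the Efron-adjusted risk-set mean, matching R's ``residuals.coxph``.
    Returns ``(event_times, residuals)`` with residuals of shape
    (n_events, p).
    """
    Xs = sd.sort_X(X)
    eta = Xs @ fit.beta
    S0, S1, _, D0, D1, _, _, _ = _suffix_sums(sd, Xs, eta)
    d = sd.death_counts
    res = np.empty((sd.n_events, Xs.shape[1]))
    times = np.empty(sd.n_events)
    ev = sd.event_idx
    k = 0
    for g in range(d.size):
        for l in range(d[g]):
            frac = l / d[g]
            mu = (S1[g] - frac * D1[g]) / (S0[g] - frac * D0[g])
            res[k] = Xs[ev[sd.death_start[g] + l]] - mu
            times[k] = sd.group_times[g]
            k += 1
    return times, res


def _km_transform(sd: SurvData):
    """Left-continuous Kaplan–Meier estimate evaluated at each event."""
    # KM over the whole sample on the sorted data
    n_at_risk = sd.n - sd.risk_start
    km = np.cumprod(1.0 - sd.death_counts / n_at_risk)
    # value just BEFORE each event time (R's cox.zph 'km' transform)
    km_before = np.concatenate([[1.0], km[:-1]])
    per_event = np.repeat(km_before, sd.death_counts)
    return 1.0 - per_event


def zph_test(fit: CoxFit, sd: SurvData, X, transform: str = "km"):
    """Score test for proportional hazards (scaled Schoenfeld residuals).

    Tests, per covariate and globally, whether the Schoenfeld residuals
    trend with (transformed) event time — the Grambsch–Therneau test that
    R's ``cox.zph`` performs.  ``transform`` is ``"km"`` (default, one minus
    the left-continuous KM estimate at the event time), ``"rank"`` or
    ``"identity"``.

    Returns
    -------
    dict with ``p`` (per-term array), ``chi2`` (per-term array),
    ``global_p`` and ``global_chi2``.
    """
    if sd.n_events < 3:
        raise ValueError("proportional-hazards test needs at least 3 events")
    times, resid = schoenfeld_residuals(fit, sd, X)
    d = resid.shape[0]
    if transform == "km":
        g = _km_transform(sd)
    elif transform == "rank":
        g = stats.rankdata(times)
    elif transform == "identity":
        g = times.copy()
    else:
        raise ValueError(f"unknown transform {transform!r}")
    g = g - g.mean()
    gg = float(g @ g)
    if gg == 0:
        raise ValueError("degenerate time transform (all events tied)")

    # scaled residuals s* = d * V^{-1} s ; the additive beta-hat term drops
    # out because g is centered
    sstar = d * resid @ fit.cov
    u = g @ sstar                                   # per-term numerators
    chi2 = u**2 / (d * np.diag(fit.cov) * gg)
    p = stats.chi2.sf(chi2, 1)

    u_raw = g @ resid
    global_chi2 = float(u_raw @ fit.cov @ u_raw) * d / gg
    global_p = float(stats.chi2.sf(global_chi2, resid.shape[1]))
    return {"chi2": chi2, "p": p, "global_chi2": global_chi2, "global_p": global_p}
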