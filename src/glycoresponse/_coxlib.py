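"""Vectorised Efron partial-likelihood machinery.

Newton solver for Cox proportional-hazards coefficients with Efron tie
handling and optional delayed entry (left truncation).  Risk-set structure is
precomputed once per dataset so permutation loops that only change one
covariate column can refit cheaply.  Also provides Schoenfeld residuals and
the Grambsch-Therneau global proportional-hazards statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CoxStructure:
    time: np.ndarray
    event: np.ndarray
    entry: np.ndarray
    event_times: np.ndarray  # unique, ascending
    death_sets: list  # index arrays, one per event time
    risk_sets: list  # index arrays, one per event time
    death_mask: np.ndarray  # n_event_times x n, float
    risk_mask: np.ndarray
    d_counts: np.ndarray  # deaths per event time

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def build_structure(time, event, entry=None) -> CoxStructure:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if entry is None:
        entry = np.zeros_like(time)
    else:
        entry = np.asarray(entry, dtype=float)
    if event.sum() == 0:
        raise ValueError("no events")
    event_times = np.unique(time[event == 1])
    death_mask = ((time[None, :] == event_times[:, None]) & (event[None, :] == 1)).astype(float)
    risk_mask = ((entry[None, :] < event_times[:, None]) & (time[None, :] >= event_times[:, None])).astype(float)
    death_sets = [np.flatnonzero(m) for m in death_mask]
    risk_sets = [np.flatnonzero(m) for m in risk_mask]
    return CoxStructure(
        time, event, entry, event_times, death_sets, risk_sets,
        death_mask, risk_mask, death_mask.sum(axis=1).astype(int),
    )


def loglik_grad_hess(beta: np.ndarray, X: np.ndarray, s: CoxStructure):
    """Efron partial log-likelihood with gradient and Hessian.

    Risk-set sums are evaluated for all event times at once via the
    precomputed masks; event times with tied deaths fall back to the
    per-tie Efron adjustment.
    """
    eta = X @ beta
    eta = eta - (eta.max() if len(eta) else 0.0)  # shift-invariant overflow guard
    w = np.exp(eta)
    n, p = X.shape
    wX = w[:, None] * X
    XX = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    wXX = w[:, None] * XX

    sR = s.risk_mask @ w  # (E,)
    aR = s.risk_mask @ wX  # (E, p)
    bR = s.risk_mask @ wXX  # (E, p*p)

    ll = float((s.death_mask @ eta).sum())
    grad = (s.death_mask @ X).sum(axis=0)
    hess = np.zeros((p, p))

    single = s.d_counts == 1
    if single.any():
        denom = sR[single]
        mean = aR[single] / denom[:, None]
        ll -= float(np.log(denom).sum())
        grad -= mean.sum(axis=0)
        hess -= (bR[single] / denom[:, None]).sum(axis=0).reshape(p, p)
        hess += mean.T @ mean
    for k in np.flatnonzero(~single):
        d = int(s.d_counts[k])
        D = s.death_sets[k]
        sD = w[D].sum()
        aD = wX[D].sum(axis=0)
        bD = wXX[D].sum(axis=0)
        for l in range(d):
            frac = l / d
            denom = sR[k] - frac * sD
            mean = (aR[k] - frac * aD) / denom
            ll -= np.log(denom)
            grad -= mean
            hess -= (bR[k] - frac * bD).reshape(p, p) / denom - np.outer(mean, mean)
    return ll, grad, hess


def newton_fit(
    X: np.ndarray,
    s: CoxStructure,
    beta_init=None,
    max_iter: int = 50,
    tol: float = 1e-9,
):
    """Newton-Raphson maximisation; returns (beta, loglik, cov, converged)."""
    p = X.shape[1]
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    ll_prev = -np.inf
    beta_prev = beta.copy()
    step = np.zeros(p)
    halvings = 0
    converged = False
    ll = hess = None
    for _ in range(max_iter):
        ll, grad, hess = loglik_grad_hess(beta, X, s)
        if not np.isfinite(ll) or ll < ll_prev - 1e-12:
            # overshoot: halve the last step and retry
            halvings += 1
            if halvings > 20:
                break
            step *= 0.5
            beta = beta_prev + step
            continue
        if ll - ll_prev < tol and np.max(np.abs(step)) < np.sqrt(tol):
            converged = True
            break
        if np.max(np.abs(grad)) < 1e-7:
            # likelihood plateau (e.g. a no-event factor level drifting to
            # -inf): the partial likelihood is maximised for all purposes
            converged = True
            break
        halvings = 0
        try:
            new_step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            return beta, ll, None, False
        big = np.max(np.abs(new_step))
        if big > 5.0:
            # trust region: huge Newton steps signal a flat direction
            # (monotone likelihood); walk towards the plateau gradually
            new_step = new_step * (5.0 / big)
        ll_prev, beta_prev, step = ll, beta.copy(), new_step
        beta = beta + new_step
    if not converged:
        ll, grad, hess = loglik_grad_hess(beta, X, s)
    if np.max(np.abs(beta)) > 50:
        converged = False  # monotone likelihood
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov, converged = None, False
    return beta, ll, cov, converged


def null_loglik(X_cov: np.ndarray, s: CoxStructure, beta_init=None):
    if X_cov.shape[1] == 0:
        ll, _, _ = loglik_grad_hess(np.zeros(0), np.zeros((len(s.time), 0)), s)
        return np.zeros(0), ll, True
    beta, ll, _, conv = newton_fit(X_cov, s, beta_init=beta_init)
    return beta, ll, conv


def lrt_pvalue(ll_full: float, ll_null: float, df: int = 1) -> float:
    return float(stats.chi2.sf(2.0 * (ll_full - ll_null), df))


def schoenfeld_residuals(beta: np.ndarray, X: np.ndarray, s: CoxStructure):
    """Per-event Schoenfeld residuals (risk-set weighted mean subtracted).

    Breslow-style risk-set means; with continuous times (no ties) this is the
    exact Efron quantity as well.
    """
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wX = w[:, None] * X
    resid, times = [], []
    for t, D, R in zip(s.event_times, s.death_sets, s.risk_sets):
        mean = wX[R].sum(axis=0) / w[R].sum()
        for i in D:
            resid.append(X[i] - mean)
            times.append(t)
    return np.asarray(resid), np.asarray(times)


def km_transform(times: np.ndarray, s: CoxStructure) -> np.ndarray:
    """1 - KM(t-) evaluated at the event times (left-continuous)."""
    order = np.argsort(s.time)
    t_sorted = s.time[order]
    e_sorted = s.event[order]
    uniq = np.unique(t_sorted)
    surv = 1.0
    km_at = {}
    n = len(t_sorted)
    at_risk = n
    idx = 0
    for t in uniq:
        km_at[t] = surv  # left-continuous value before drops at t
        d = int(e_sorted[(t_sorted == t)].sum())
        m = int((t_sorted == t).sum())
        if at_risk > 0 and d > 0:
            surv *= 1.0 - d / at_risk
        at_risk -= m
    return np.array([1.0 - km_at[t] for t in times])


def grambsch_therneau_global(beta, X, s, cov, transform: str = "km"):
    """Global chi-square proportional-hazards test over all model terms."""
    resid, times = schoenfeld_residuals(beta, X, s)
    d = len(times)
    if d < 3:
        raise ValueError("fewer than 3 events; PH test undefined")
    if transform == "km":
        g = km_transform(times, s)
    elif transform == "identity":
        g = times.astype(float)
    elif transform == "rank":
        g = stats.rankdata(times)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    u = gc @ resid  # p-vector
    denom = float((gc**2).sum())
    stat = d * float(u @ cov @ u) / denom
    p = float(stats.chi2.sf(stat, X.shape[1]))
    return stat, p
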