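"""Survival analysis: Kaplan-Meier, log-rank, and Cox proportional hazards.

The endpoint throughout is distant-metastasis-free survival (DMFS): time in
months from surgery to distant recurrence, with death without metastasis and
end of follow-up treated as censoring.

The Cox model maximises the partial likelihood with the Breslow
approximation for tied event times, by Newton-Raphson with step-halving;
the log partial likelihood is non-decreasing across accepted iterations and
convergence is declared when successive changes fall below ``tol`` (default
1e-9) within ``max_iter`` (default 50) iterations.  Monotone-likelihood
cases (complete separation) are returned with ``converged=False`` rather
than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "log_rank_test",
    "pairwise_log_rank",
    "cox_fit",
    "cox_score_test",
]


def _validate_times(time, event) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("need at least one survival sample")
    if t.size != e.size:
        raise ValueError("time and event must have equal length")
    if np.isnan(t).any():
        raise ValueError("survival times must not be NaN")
    if (t < 0).any():
        raise ValueError("survival times must be >= 0")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` are the sorted distinct times with at least one event;
    ``survival[i]`` is S(t) just after ``event_times[i]``; ``at_risk[i]`` and
    ``events[i]`` are the risk-set size and event count at that time.
    S(0) = 1 and the curve is a non-increasing step function.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations leave the risk set without contributing a factor;
    an input with no events yields the constant curve S(t) = 1.
    """
    t, e = _validate_times(time, event)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]

    uniq, first_idx = np.unique(t, return_index=True)
    n = t.size
    # at risk just before each distinct time = everyone with time >= that time
    at_risk_all = n - first_idx
    d = np.zeros(uniq.size)
    np.add.at(d, np.searchsorted(uniq, t[e]), 1)

    has_event = d > 0
    event_times = uniq[has_event]
    at_risk = at_risk_all[has_event]
    events = d[has_event]
    survival = np.cumprod(1.0 - events / at_risk)
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk.astype(int),
        events=events.astype(int),
    )


# ---------------------------------------------------------------------------
# Log-rank


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float
    observed: np.ndarray  # events per group
    expected: np.ndarray  # expected events per group under H0


def log_rank_test(time, event, group) -> LogRankResult:
    """k-group log-rank test of equality of survival curves.

    Sums observed-minus-expected events over the risk set at each distinct
    event time; the statistic is the quadratic form of the first k-1
    components in the hypergeometric covariance, chi-square with k-1 df
    under the null.
    """
    t, e = _validate_times(time, event)
    g = np.asarray(group)
    if g.size != t.size:
        raise ValueError("group labels must align with times")
    labels, gidx = np.unique(g, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(gidx, minlength=k)
    if (counts == 0).any():
        raise ValueError("every group must contain at least one subject")

    event_times = np.unique(t[e])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk_mask = t >= et
        n_j = np.bincount(gidx[at_risk_mask], minlength=k).astype(float)
        N = n_j.sum()
        dead_mask = (t == et) & e
        d_j = np.bincount(gidx[dead_mask], minlength=k).astype(float)
        D = d_j.sum()
        O += d_j
        E += D * n_j / N
        if N > 1:
            # multivariate hypergeometric covariance of d_j
            f = D * (N - D) / (N - 1) / N**2
            V += f * (np.diag(n_j * N) - np.outer(n_j, n_j))

    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return LogRankResult(statistic=stat, df=df, p=p, observed=O, expected=E)


def pairwise_log_rank(time, event, group, reference) -> Dict[object, LogRankResult]:
    """Two-group log-rank of every other group against ``reference``.

    Mirrors survival-curve figures annotated "compared to the High group":
    one p-value per non-reference group.
    """
    t, e = _validate_times(time, event)
    g = np.asarray(group)
    labels = np.unique(g)
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} not present")
    out: Dict[object, LogRankResult] = {}
    for lab in labels:
        if lab == reference:
            continue
        mask = (g == lab) | (g == reference)
        out[lab] = log_rank_test(t[mask], e[mask], g[mask])
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)


@dataclass(frozen=True)
class CoxFit:
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_iter: int
    covariate_names: Optional[List[str]] = None
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> "object":
        """Coefficient table as a pandas DataFrame."""
        import pandas as pd

        names = self.covariate_names or [f"x{i}" for i in range(self.coefficients.size)]
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "se": self.standard_errors,
                "p": self.p_values,
            },
            index=names,
        )


def _breslow_loglik_grad_hess(beta, X, t, e):
    """Log partial likelihood, gradient, Hessian under Breslow ties.

    Works on data pre-sorted by descending time so the risk set at each
    event time is a prefix in that order.
    """
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # cumulative sums over the descending-time ordering
    S0 = np.cumsum(w)
    S1 = np.cumsum(X * w[:, None], axis=0)
    S2 = np.cumsum(np.einsum("ni,nj->nij", X, X) * w[:, None, None], axis=0)

    # risk set at time t includes the full tie block: take cumsum at the last
    # index of each distinct time (descending order -> last index of block)
    uniq_t, inv = np.unique(-t, return_inverse=True)  # ascending over -t == descending t
    block_last = np.zeros(uniq_t.size, dtype=int)
    np.maximum.at(block_last, inv, np.arange(t.size))

    ll = 0.0
    grad = np.zeros(X.shape[1])
    hess = np.zeros((X.shape[1], X.shape[1]))
    ev_idx = np.flatnonzero(e)
    if ev_idx.size == 0:
        raise ValueError("no events: partial likelihood undefined")
    ll += float(eta[ev_idx].sum())
    grad += X[ev_idx].sum(axis=0)
    # per distinct event time: d_t * [log S0, S1/S0, S2/S0 - outer]
    ev_blocks = inv[ev_idx]
    d_per_block = np.bincount(ev_blocks, minlength=uniq_t.size)
    for b in np.flatnonzero(d_per_block):
        j = block_last[b]
        d = d_per_block[b]
        s0 = S0[j]
        s1 = S1[j]
        s2 = S2[j]
        ll -= d * np.log(s0)
        grad -= d * s1 / s0
        hess += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
    return ll, grad, hess


def cox_fit(
    X,
    time,
    event,
    covariate_names: Optional[Sequence[str]] = None,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Ties are handled by the Breslow approximation.  Step-halving guards each
    Newton step so the log partial likelihood never decreases; Wald standard
    errors come from the inverse observed information at the optimum.

    Raises
    ------
    ValueError
        If there are no events, or shapes are inconsistent.
    """
    t, e = _validate_times(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != t.size:
        raise ValueError("covariate rows must align with times")
    if not e.any():
        raise ValueError("no events: Cox model cannot be fit")

    # center covariates for numerical stability (coefficients unaffected)
    X_mean = X.mean(axis=0)
    Xc = X - X_mean

    order = np.argsort(-t, kind="mergesort")
    Xs, ts, es = Xc[order], t[order], e[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _breslow_loglik_grad_hess(beta, Xs, ts, es)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving: accept only non-decreasing log partial likelihood
        alpha = 1.0
        accepted = False
        for _ in range(30):
            cand = beta + alpha * step
            ll_new, grad_new, hess_new = _breslow_loglik_grad_hess(cand, Xs, ts, es)
            if ll_new >= ll - 1e-12:
                accepted = True
                break
            alpha /= 2.0
        if not accepted:
            break
        beta, grad, hess = cand, grad_new, hess_new
        path.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        coefficients=beta,
        hazard_ratios=np.exp(beta),
        standard_errors=se,
        p_values=pvals,
        log_partial_likelihood=float(ll),
        converged=converged,
        n_iter=it,
        covariate_names=list(covariate_names) if covariate_names is not None else None,
        loglik_path=np.asarray(path),
    )


def cox_score_test(X, time, event) -> Tuple[float, float]:
    """Score (Rao) test of beta = 0 in the Cox model.

    With a single binary covariate and no tied event times this statistic
    equals the two-group log-rank statistic (classical equivalence).
    Returns ``(statistic, p)`` with df = number of covariates.
    """
    t, e = _validate_times(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xc = X - X.mean(axis=0)
    order = np.argsort(-t, kind="mergesort")
    _, grad, hess = _breslow_loglik_grad_hess(np.zeros(X.shape[1]), Xc[order], t[order], e[order])
    stat = float(grad @ np.linalg.solve(hess, grad))
    return stat, float(stats.chi2.sf(stat, X.shape[1]))
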