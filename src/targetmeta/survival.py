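"""Survival association of target expression: median split, Kaplan-Meier,
log-rank and univariate Cox proportional hazards.

Samples are split at the median of the target's expression (ties to the low
group).  The Kaplan-Meier curves and log-rank test come from lifelines; the
univariate Cox model is a Newton optimization of the partial likelihood
with Efron handling of tied event times.  A covariate is called a risk
factor when its hazard ratio exceeds 1 and the log-rank p (on the median
split) is below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class CoxResult:
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_logrank: float
    risk_factor: bool


def median_split(values) -> np.ndarray:
    """Label each value "high" (> median) or "low" (<= median)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise SurvivalError("median split needs n >= 4")
    if np.ptp(x) == 0:
        raise SurvivalError("all values identical; no split possible")
    med = float(np.median(x))
    return np.where(x > med, "high", "low")


def km_estimator(times, events) -> pd.DataFrame:
    """Product-limit survival curve for one group.

    Returns a frame with columns ``time`` and ``survival``; the curve starts
    at S(0) = 1 and is non-increasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise SurvivalError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(times, events, groups):
    """Two-group log-rank test; returns (chi2, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise SurvivalError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if events.sum() < 1:
        raise SurvivalError("log-rank needs at least one event")
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], event_observed_A=events[a],
                      event_observed_B=events[~a])
    return float(res.test_statistic), float(res.p_value)


def _cox_loglik_derivs(beta: float, x: np.ndarray, times: np.ndarray,
                       events: np.ndarray, ties: str):
    """Partial log-likelihood with first/second derivative at scalar beta.

    Efron or Breslow correction for tied event times.  Samples must be
    pre-sorted by time ascending.
    """
    eta = beta * x
    w = np.exp(eta)
    wx = w * x
    wx2 = w * x * x
    # suffix sums over the risk set {j : t_j >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1])[::-1]
    S2 = np.cumsum(wx2[::-1])[::-1]

    ll = 0.0
    grad = 0.0
    hess = 0.0
    n = len(x)
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        d_idx = np.arange(i, j)[events[i:j] == 1]
        d = len(d_idx)
        if d > 0:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            d0 = w[d_idx].sum()
            d1 = wx[d_idx].sum()
            d2 = wx2[d_idx].sum()
            ll += eta[d_idx].sum()
            grad += x[d_idx].sum()
            for ell in range(d):
                f = ell / d if ties == "efron" else 0.0
                phi0 = s0 - f * d0
                phi1 = s1 - f * d1
                phi2 = s2 - f * d2
                ll -= np.log(phi0)
                grad -= phi1 / phi0
                hess -= phi2 / phi0 - (phi1 / phi0) ** 2
        i = j
    return ll, grad, hess


def cox_univariate(covariate, times, events, ties: str = "efron",
                   max_iter: int = 50, tol: float = 1e-10) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton's method.

    Returns the hazard ratio exp(beta) with a Wald 95% CI on the log scale,
    the Wald p, and the log-rank p computed on the median split of the
    covariate.  ``risk_factor`` is true when hr > 1 and p_logrank < 0.05.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.ptp(x) == 0:
        raise SurvivalError("constant covariate")
    if e.sum() < 1:
        raise SurvivalError("no events")
    order = np.argsort(t, kind="stable")
    x, t, e = x[order], t[order], e[order]
    # standardize for numerical stability; beta rescales exactly
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd

    beta = 0.0
    for _ in range(max_iter):
        _, grad, hess = _cox_loglik_derivs(beta, xs, t, e, ties)
        if hess >= 0:
            raise SurvivalError("non-concave step in Cox optimization")
        step = grad / -hess
        beta += step
        if abs(step) < tol:
            break
    else:
        raise SurvivalError(f"Cox Newton did not converge in {max_iter} iterations")

    _, _, hess = _cox_loglik_derivs(beta, xs, t, e, ties)
    se_s = float(np.sqrt(-1.0 / hess))
    b = beta / sd
    se = se_s / sd
    z = b / se
    p_wald = float(2.0 * stats.norm.sf(abs(z)))
    try:
        grp = median_split(x)
        _, p_lr = logrank_test(t, e, grp)
    except SurvivalError:
        p_lr = 1.0
    hr = float(np.exp(b))
    return CoxResult(float(b), hr, float(np.exp(b - 1.96 * se)),
                     float(np.exp(b + 1.96 * se)), p_wald, float(p_lr),
                     bool(hr > 1 and p_lr < 0.05))
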