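"""Fast survival statistics shared by the cut-point and forest modules.

The centile-grid analysis fits on the order of 10^4 single-covariate
Cox models and the forest evaluates ~10^2 candidate log-rank splits per
tree node, so both primitives are implemented directly on numpy arrays:
a Newton-Raphson proportional-hazards solver with Efron tie handling
and a vectorised two-group log-rank statistic that scores many
candidate group assignments in one pass.  ``lifelines`` remains the
reference implementation for Kaplan-Meier curves (Greenwood-type
confidence intervals) and serves as the cross-check for the solvers in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _as_surv_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("time and event must be matched 1-D arrays")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return t, e


# ---------------------------------------------------------------------------
# Cox proportional hazards, single covariate, Efron ties


@dataclass(frozen=True)
class CoxResult:
    """Single-covariate proportional-hazards fit."""

    coef: float
    se: float
    z: float
    p: float
    n: int
    n_events: int
    converged: bool


def cox_fit_single(
    x, time, event, *, max_iter: int = 60, tol: float = 1e-10
) -> CoxResult:
    """Newton-Raphson Cox regression of survival on one covariate.

    Ties are handled with the Efron approximation.  Raises
    ``ValueError`` when fewer than 2 events are present or the
    covariate does not vary (the partial likelihood is flat).
    """
    x = np.asarray(x, dtype=float)
    t, e = _as_surv_arrays(time, event)
    if x.shape != t.shape:
        raise ValueError("covariate and survival arrays must be matched")
    if e.sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: Cox model is unidentifiable")

    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    x = x - x.mean()  # centring for numerical stability; coef unchanged
    n = t.size
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    death_groups = []
    bounds = np.r_[starts, n]
    for g in range(starts.size):
        idx = np.arange(bounds[g], bounds[g + 1])
        idx = idx[e[idx] == 1]
        if idx.size:
            death_groups.append((g, idx))

    def derivs(b: float) -> tuple[float, float, float]:
        w = np.exp(b * x)
        xw = x * w
        x2w = x * xw
        S0 = np.cumsum(w[::-1])[::-1][starts]
        S1 = np.cumsum(xw[::-1])[::-1][starts]
        S2 = np.cumsum(x2w[::-1])[::-1][starts]
        ll = u = info = 0.0
        for g, idx in death_groups:
            dg = idx.size
            frac = np.arange(dg) / dg
            s0 = S0[g] - frac * w[idx].sum()
            s1 = S1[g] - frac * xw[idx].sum()
            s2 = S2[g] - frac * x2w[idx].sum()
            ll += b * x[idx].sum() - np.log(s0).sum()
            r1 = s1 / s0
            u += x[idx].sum() - r1.sum()
            info += (s2 / s0 - r1**2).sum()
        return ll, u, info

    b = 0.0
    ll, u, info = derivs(b)
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = u / info
        step = np.clip(step, -5.0, 5.0)
        b_new = b + step
        ll_new, u_new, info_new = derivs(b_new)
        # step-halving if the likelihood worsens
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 20:
            step /= 2.0
            b_new = b + step
            ll_new, u_new, info_new = derivs(b_new)
            halvings += 1
        if abs(b_new - b) < tol or abs(u_new) < tol:
            b, ll, u, info = b_new, ll_new, u_new, info_new
            converged = True
            break
        b, ll, u, info = b_new, ll_new, u_new, info_new

    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = b / se if np.isfinite(se) and se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(
        coef=float(b),
        se=float(se),
        z=float(z),
        p=float(max(p, np.finfo(float).tiny)),
        n=int(n),
        n_events=int(e.sum()),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# log-rank


def logrank_statistics(time, event, membership) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank chi-square for many candidate group assignments.

    ``membership`` is an (n, K) boolean matrix; column k defines group 1
    of candidate split k.  Returns (chi2, p) arrays of length K.  The
    statistic is the classic risk-table form: at each event time with
    ``d`` deaths among ``Y`` at risk (``Y1`` in group 1, ``d1`` deaths
    in group 1), observed-minus-expected ``d1 - d*Y1/Y`` accumulates
    with hypergeometric variance ``d*(Y1/Y)*(1-Y1/Y)*(Y-d)/(Y-1)``.
    Splits with zero variance (one group empty) return chi2 = 0, p = 1.
    """
    t, e = _as_surv_arrays(time, event)
    M = np.asarray(membership)
    if M.ndim == 1:
        M = M[:, None]
    M = M.astype(float)
    order = np.argsort(t, kind="stable")
    t, e, M = t[order], e[order], M[order]
    n = t.size
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, starts)
    Y = n - starts
    cnt1 = np.add.reduceat(M, starts, axis=0)
    d1 = np.add.reduceat(e[:, None] * M, starts, axis=0)
    # group-1 at risk just before each unique time: suffix sums
    Y1 = np.cumsum(cnt1[::-1], axis=0)[::-1]

    ev = d > 0
    frac = Y1[ev] / Y[ev, None]
    dm = d[ev, None]
    Ym = Y[ev, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        var_term = np.where(
            Ym > 1, dm * frac * (1 - frac) * (Ym - dm) / (Ym - 1), 0.0
        )
    observed_minus_expected = (d1[ev] - dm * frac).sum(axis=0)
    variance = var_term.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(variance > 0, observed_minus_expected**2 / variance, 0.0)
    p = np.where(variance > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def logrank_test(time, event, group) -> tuple[float, float]:
    """Plain two-group log-rank test; returns (chi2, p)."""
    chi2, p = logrank_statistics(time, event, np.asarray(group, dtype=bool))
    return float(chi2[0]), float(p[0])


# ---------------------------------------------------------------------------
# Kaplan-Meier


def kaplan_meier_curves(
    time, event, group=None, conf: float = 0.95
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves with confidence intervals per group.

    Uses lifelines' Kaplan-Meier fitter (Greenwood-type, exponential
    log-log confidence intervals).  With no groups a single curve keyed
    ``"all"`` is returned; curves are non-increasing step functions
    starting at 1.
    """
    from lifelines import KaplanMeierFitter

    t, e = _as_surv_arrays(time, event)
    if group is None:
        group = np.full(t.size, "all")
    group = np.asarray(group)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(group):
        m = group == g
        if not m.any():
            continue
        kmf = KaplanMeierFitter(alpha=1 - conf)
        kmf.fit(t[m], e[m], label=str(g))
        ci = kmf.confidence_interval_
        out[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "ci_lower": ci.iloc[:, 0].to_numpy(),
                "ci_upper": ci.iloc[:, 1].to_numpy(),
            }
        )
    return out
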