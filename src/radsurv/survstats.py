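"""Survival evaluation statistics.

Implements the evaluation battery used to judge a risk score against
right-censored outcomes: Kaplan-Meier curves with Greenwood variance,
the log-rank test, Harrell's C with bootstrap confidence intervals and a
jackknifed U-statistic comparison of two C-indices, IPCW time-dependent
ROC analysis with Youden cutoff selection, Hosmer-Lemeshow calibration,
survival-adapted decision curves, IDI / continuous NRI increments, a
Newton-Raphson Cox proportional-hazards fitter (Breslow ties) and an
exact-when-feasible Wilcoxon signed-rank test.

All estimators are plain functions over numpy arrays; dataclasses carry
the structured results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._concordance import concordance_index, pair_row_stats

__all__ = [
    "KMCurve",
    "TimeROC",
    "CoxFit",
    "kaplan_meier",
    "km_prob_at",
    "log_rank",
    "cindex_ci",
    "compare_cindex",
    "time_roc",
    "calibration_3yr",
    "risk_to_prob",
    "decision_curve",
    "idi_nri",
    "fit_cox",
    "wilcoxon_signed_rank",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate over the observed event times."""

    times: np.ndarray           # unique observed times (events and censorings)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray        # S(t) just after each time
    variance: np.ndarray        # Greenwood variance of S(t)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.variance)


def kaplan_meier(time, event) -> KMCurve:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty sample")

    times = np.unique(time)
    surv = np.empty_like(times)
    var = np.empty_like(times)
    n_at_risk = np.empty_like(times, dtype=int)
    n_events = np.empty_like(times, dtype=int)

    s = 1.0
    gw = 0.0  # running Greenwood sum d / (n (n - d))
    for k, t in enumerate(times):
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        n_at_risk[k] = n
        n_events[k] = d
        if d > 0:
            s *= 1.0 - d / n
            if n > d:
                gw += d / (n * (n - d))
            else:
                gw = np.inf  # survival hits zero; variance degenerate
        surv[k] = s
        var[k] = 0.0 if s == 0.0 else s * s * gw
    return KMCurve(times, n_at_risk, n_events, surv, var)


def km_prob_at(curve: KMCurve, t: float) -> float:
    """S(t) from the step function; 1.0 before the first observed time."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


def log_rank(time, event, group):
    """K-sample log-rank test.

    Returns ``(chi2, df, p)`` using the observed-minus-expected statistic
    with hypergeometric variance, df = k - 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if event.sum() < 1:
        raise ValueError("log-rank needs >= 1 event")

    event_times = np.unique(time[event == 1])
    omeo = np.zeros(k)                  # observed minus expected per group
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        d = int(((time == t) & (event == 1)).sum())
        if n <= 1:
            # variance term vanishes; expectation still contributes
            pass
        n_g = np.array([(at_risk & (group == lab)).sum() for lab in labels])
        d_g = np.array(
            [((time == t) & (event == 1) & (group == lab)).sum() for lab in labels]
        )
        e_g = n_g * d / n
        omeo += d_g - e_g
        if n > 1:
            c = d * (n - d) / (n - 1)
            cov += c * (np.diag(n_g) / n - np.outer(n_g, n_g) / n**2)

    v = omeo[:-1]
    V = cov[:-1, :-1]
    try:
        chi2 = float(v @ np.linalg.solve(V, v))
    except np.linalg.LinAlgError:
        chi2 = float(v @ np.linalg.pinv(V) @ v)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# C-index: CI and paired comparison
# ---------------------------------------------------------------------------


def cindex_ci(score, time, event, n_boot: int = 2000, seed: int = 0):
    """Harrell's C with a percentile-bootstrap 95% CI over patients."""
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    c = concordance_index(score, time, event)

    rng = np.random.default_rng(seed)
    n = len(score)
    reps = []
    attempts = 0
    while len(reps) < n_boot and attempts < 4 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(concordance_index(score[idx], time[idx], event[idx]))
        except ValueError:
            continue  # resample produced no usable pairs
    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(c), float(lo), float(hi)


def compare_cindex(score_a, score_b, time, event):
    """Two-sided p for C(a) = C(b) on the same patients.

    Uses the jackknife estimate of the variance of the paired C difference
    (a delete-one approximation to the U-statistic variance).
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)

    ca_rows, wa_rows, ca_tot, wa_tot = pair_row_stats(score_a, time, event)
    cb_rows, wb_rows, cb_tot, wb_tot = pair_row_stats(score_b, time, event)

    diff = ca_tot / wa_tot - cb_tot / wb_tot
    if np.array_equal(score_a, score_b):
        return 1.0

    # leave-one-out differences
    with np.errstate(invalid="ignore", divide="ignore"):
        ca_loo = (ca_tot - ca_rows) / (wa_tot - wa_rows)
        cb_loo = (cb_tot - cb_rows) / (wb_tot - wb_rows)
    d_loo = ca_loo - cb_loo
    ok = np.isfinite(d_loo)
    d_loo = d_loo[ok]
    m = len(d_loo)
    var = (m - 1) / m * np.sum((d_loo - d_loo.mean()) ** 2)
    if var <= 0:
        return 1.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Time-dependent ROC (IPCW cumulative/dynamic)
# ---------------------------------------------------------------------------


@dataclass
class TimeROC:
    horizon: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float


def _censoring_km(time, event) -> KMCurve:
    """KM of the censoring distribution (censorings are the 'events')."""
    return kaplan_meier(time, 1 - np.asarray(event, dtype=int))


def time_roc(score, time, event, horizon: float) -> TimeROC:
    """Cumulative-case / dynamic-control ROC at ``horizon``.

    Cases: observed events by the horizon, weighted 1/G(T-); controls:
    patients still at risk after the horizon, weighted 1/G(horizon), with
    G the Kaplan-Meier estimate of the censoring survival function.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if horizon > time.max():
        raise ValueError(
            f"horizon {horizon} exceeds last observed time {time.max()}"
        )

    G = _censoring_km(time, event)

    case = (time <= horizon) & (event == 1)
    ctrl = time > horizon
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("need at least one case and one control at horizon")

    w = np.zeros(len(time))
    for i in np.where(case)[0]:
        g = km_prob_at(G, time[i] - 1e-9)  # G(T-)
        w[i] = 1.0 / g if g > 0 else 0.0
    g_h = km_prob_at(G, horizon)
    w[ctrl] = 1.0 / g_h if g_h > 0 else 0.0

    s_case, w_case = score[case], w[case]
    s_ctrl, w_ctrl = score[ctrl], w[ctrl]
    wc = w_case.sum()
    wn = w_ctrl.sum()

    cutoffs = np.unique(score)
    sens = np.array([(w_case[s_case > c]).sum() / wc for c in cutoffs])
    spec = np.array([(w_ctrl[s_ctrl <= c]).sum() / wn for c in cutoffs])

    # weighted probability a random case outranks a random control
    gt = (s_case[:, None] > s_ctrl[None, :]).astype(float)
    eq = (s_case[:, None] == s_ctrl[None, :]).astype(float)
    auc = float(((gt + 0.5 * eq) * np.outer(w_case, w_ctrl)).sum() / (wc * wn))

    youden = sens + spec - 1.0
    cut = float(cutoffs[int(np.argmax(youden))])
    return TimeROC(horizon, cutoffs, sens, spec, auc, cut)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibration_3yr(predicted_prob, time, event, horizon: float = 36.0,
                    n_groups: int = 10, df: int | None = None):
    """Grouped calibration of predicted event probabilities at ``horizon``.

    Patients are cut into ``n_groups`` quantile groups of predicted
    probability; the observed event fraction per group is 1 - KM(horizon)
    within the group.  Returns ``(table, chi2, p)`` with the
    Hosmer-Lemeshow statistic on ``n_groups - 2`` degrees of freedom by
    default (the in-sample convention); pass ``df=n_groups`` when the
    probabilities come from an external model.
    """
    p = np.asarray(predicted_prob, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")

    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_groups + 1)))
    if len(edges) - 1 < 2:
        raise ValueError(
            "degenerate predictions: fewer than 2 usable groups; "
            "reduce n_groups"
        )
    grp = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)

    rows = []
    chi2 = 0.0
    g_used = 0
    for g in range(len(edges) - 1):
        sel = grp == g
        n_g = int(sel.sum())
        if n_g == 0:
            continue
        pbar = p[sel].mean()
        km = kaplan_meier(time[sel], event[sel])
        obs = 1.0 - km_prob_at(km, horizon)
        rows.append((g, n_g, pbar, obs))
        denom = n_g * pbar * (1.0 - pbar)
        if denom > 0:
            chi2 += (n_g * obs - n_g * pbar) ** 2 / denom
            g_used += 1
    if df is None:
        df = max(g_used - 2, 1)
    p_val = float(stats.chi2.sf(chi2, df))
    return rows, float(chi2), p_val


def risk_to_prob(score, time, event, horizon: float):
    """Predicted event probability by ``horizon`` from a risk score.

    Fits a one-covariate Cox model on the score and converts via the
    Breslow baseline cumulative hazard:
    ``P = 1 - exp(-H0(horizon) * exp(beta * score))``.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)

    if np.ptp(score) == 0:
        eta = np.zeros_like(score)
    else:
        fit = fit_cox(score[:, None], time, event)
        eta = fit.coef[0] * score

    # Breslow baseline: H0(t) = sum_{event times <= t} d_i / sum_{at risk} exp(eta)
    r = np.exp(eta)
    h0 = 0.0
    for t in np.unique(time[event == 1]):
        if t > horizon:
            break
        d = int(((time == t) & (event == 1)).sum())
        denom = r[time >= t].sum()
        h0 += d / denom
    prob = 1.0 - np.exp(-h0 * r)
    return np.clip(prob, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Decision curves
# ---------------------------------------------------------------------------


def decision_curve(predicted_prob, time, event, horizon: float, thresholds):
    """Survival-adapted net benefit at each threshold.

    NB(p_t) = TP/n - FP/n * p_t / (1 - p_t) where, among patients with
    predicted probability >= p_t, the true/false positive fractions come
    from the group Kaplan-Meier estimate at ``horizon``.  Also returns the
    treat-all and treat-none reference curves.
    """
    p = np.asarray(predicted_prob, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    thresholds = np.asarray(thresholds, dtype=float)
    n = len(p)

    km_all = kaplan_meier(time, event)
    rate = 1.0 - km_prob_at(km_all, horizon)

    nb = np.zeros(len(thresholds))
    nb_all = np.zeros(len(thresholds))
    for k, pt in enumerate(thresholds):
        odds = pt / (1.0 - pt)
        nb_all[k] = rate - (1.0 - rate) * odds
        pos = p >= pt
        if pos.sum() == 0:
            nb[k] = 0.0
            continue
        km_pos = kaplan_meier(time[pos], event[pos])
        risk_pos = 1.0 - km_prob_at(km_pos, horizon)
        frac = pos.sum() / n
        tp = frac * risk_pos
        fp = frac * (1.0 - risk_pos)
        nb[k] = tp - fp * odds
    nb_none = np.zeros(len(thresholds))
    return {"thresholds": thresholds, "net_benefit": nb,
            "treat_all": nb_all, "treat_none": nb_none}


# ---------------------------------------------------------------------------
# IDI / continuous NRI
# ---------------------------------------------------------------------------


def _ipcw_case_control(time, event, horizon):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    G = _censoring_km(time, event)
    case = (time <= horizon) & (event == 1)
    ctrl = time > horizon
    w = np.zeros(len(time))
    for i in np.where(case)[0]:
        g = km_prob_at(G, time[i] - 1e-9)
        w[i] = 1.0 / g if g > 0 else 0.0
    g_h = km_prob_at(G, horizon)
    w[ctrl] = 1.0 / g_h if g_h > 0 else 0.0
    return case, ctrl, w


def _idi_nri_point(p_new, p_old, case, ctrl, w):
    wc, wn = w[case].sum(), w[ctrl].sum()
    slope_new = np.average(p_new[case], weights=w[case]) - \
        np.average(p_new[ctrl], weights=w[ctrl])
    slope_old = np.average(p_old[case], weights=w[case]) - \
        np.average(p_old[ctrl], weights=w[ctrl])
    idi = slope_new - slope_old

    d = p_new - p_old
    up_case = w[case & (d > 0)].sum() / wc
    dn_case = w[case & (d < 0)].sum() / wc
    up_ctrl = w[ctrl & (d > 0)].sum() / wn
    dn_ctrl = w[ctrl & (d < 0)].sum() / wn
    nri = (up_case - dn_case) + (dn_ctrl - up_ctrl)
    return idi, nri


def idi_nri(prob_new, prob_old, time, event, horizon: float,
            n_boot: int = 500, seed: int = 0):
    """IDI and continuous NRI of ``prob_new`` over ``prob_old`` at a horizon.

    Event status by the horizon is handled with IPCW weights (censored-
    before-horizon patients are dropped, survivors and observed events are
    inverse-probability weighted).  p-values are percentile-bootstrap
    two-sided tests of the null of zero increment.
    """
    p_new = np.asarray(prob_new, dtype=float)
    p_old = np.asarray(prob_old, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    case, ctrl, w = _ipcw_case_control(time, event, horizon)
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("need cases and controls at the horizon")
    idi, nri = _idi_nri_point(p_new, p_old, case, ctrl, w)

    rng = np.random.default_rng(seed)
    n = len(time)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            c, t, ww = _ipcw_case_control(time[idx], event[idx], horizon)
            if c.sum() == 0 or t.sum() == 0:
                continue
            boots.append(_idi_nri_point(p_new[idx], p_old[idx], c, t, ww))
        except ValueError:
            continue
    boots = np.asarray(boots) if boots else np.empty((0, 2))

    def _boot_p(stat, col):
        if len(boots) < 10 or stat == 0:
            return 1.0
        se = boots[:, col].std(ddof=1)
        if se == 0:
            return 1.0
        return float(2.0 * stats.norm.sf(abs(stat) / se))

    return {
        "idi": float(idi),
        "nri": float(nri),
        "idi_p": _boot_p(idi, 0),
        "nri_p": _boot_p(nri, 1),
    }


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    log_likelihood: float
    c_index: float
    names: list = field(default_factory=list)
    converged: bool = True

    def linear_predictor(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef


def _cox_quantities(beta, X, time, event):
    """(negative) partial log-likelihood with gradient and Hessian, Breslow."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    Xs = X[order]
    ts = time[order]
    es = event[order]
    eta = Xs @ beta
    eta_max = eta.max()
    r = np.exp(eta - eta_max)

    S0 = np.cumsum(r)
    S1 = np.cumsum(r[:, None] * Xs, axis=0)
    S2 = np.cumsum(r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    # risk set of an event at t = everyone with time >= t -> last index of tie block
    last = np.searchsorted(-ts, -ts, side="right") - 1

    ev = np.where(es == 1)[0]
    k = last[ev]
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        s0 = S0[k]                       # (m,)
        xbar = S1[k] / s0[:, None]       # (m, p)
        ll = float(((eta[ev] - eta_max) - np.log(s0)).sum())
        grad = (Xs[ev] - xbar).sum(axis=0)
        hess = (S2[k] / s0[:, None, None]
                - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return ll, grad, hess


def fit_cox(covariates, time, event, max_iter: int = 100, tol: float = 1e-8,
            names=None) -> CoxFit:
    """Cox PH fit by Newton-Raphson on the Breslow partial likelihood."""
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if event.sum() < 1:
        raise ValueError("Cox fit needs at least one event")

    beta = np.zeros(p)
    converged = False
    ll, grad, hess = _cox_quantities(beta, X, time, event)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step halving to guarantee likelihood increase
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _cox_quantities(cand, X, time, event)
            if ll_new >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_new, g_new, h_new
                break
            scale *= 0.5
        else:
            break
    if np.any(np.abs(beta) > 20):
        warnings.warn("possible monotone likelihood (separation); "
                      "coefficients capped at last iterate")
    elif not converged and np.linalg.norm(grad) >= tol:
        warnings.warn("Cox fit did not fully converge")

    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = np.divide(beta, se, out=np.zeros(p), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(se > 0, pvals, 1.0)
    hr = np.exp(beta)
    with np.errstate(over="ignore"):
        ci_lo = np.exp(beta - 1.959963984540054 * se)
        ci_hi = np.exp(beta + 1.959963984540054 * se)
    eta = X @ beta
    try:
        c = concordance_index(eta, time, event)
    except ValueError:
        c = float("nan")
    return CoxFit(beta, se, hr, ci_lo, ci_hi, pvals, float(ll), float(c),
                  names=list(names) if names is not None else
                  [f"x{i}" for i in range(p)],
                  converged=converged)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Exact null distribution when the non-zero differences number <= 25 and
    carry no tied absolute values; normal approximation with tie and
    continuity handling otherwise.  Identical vectors give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    abs_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not abs_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.pvalue)
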