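"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (explicit loops, enumeration) and
shares no code with the implementations under test.
"""

import itertools

import numpy as np


def brute_cindex(score, time, event):
    """O(n^2) pair enumeration of Harrell's C."""
    conc = ties = usable = 0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                pass
            elif time[i] == time[j] and event[i] == 1 and event[j] == 0:
                pass
            else:
                continue
            usable += 1
            if score[i] > score[j]:
                conc += 1
            elif score[i] == score[j]:
                ties += 1
    if usable == 0:
        raise ValueError("no usable pairs")
    return (conc + 0.5 * ties) / usable


def brute_cox_nll(risk, time, event):
    """Negative log partial likelihood with explicit risk-set loops."""
    total = 0.0
    n = len(risk)
    for i in range(n):
        if event[i] != 1:
            continue
        denom = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                denom += np.exp(risk[j])
        total -= risk[i] - np.log(denom)
    return total


def brute_cox_loglik(beta, x, time, event):
    """Partial log-likelihood of a single-covariate Cox model (Breslow)."""
    ll = 0.0
    for i in range(len(x)):
        if event[i] != 1:
            continue
        denom = sum(np.exp(beta * x[j]) for j in range(len(x))
                    if time[j] >= time[i])
        ll += beta * x[i] - np.log(denom)
    return ll


def brute_logrank_2group(time, event, group):
    """Two-group log-rank chi-square from a hand-built O/E table."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - n1 * d / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
    return o_minus_e**2 / var


def brute_censoring_km(time, event, t):
    """Product-limit estimate of the censoring survival G(t), from scratch."""
    g = 1.0
    for u in sorted(set(time)):
        if u > t:
            break
        n = (time >= u).sum()
        d = ((time == u) & (event == 0)).sum()  # censorings are events of G
        if d > 0:
            g *= 1.0 - d / n
    return g


def brute_time_auc(score, time, event, horizon):
    """IPCW cumulative/dynamic AUC via explicit double loops."""
    n = len(score)
    cases, ctrls, w_case, w_ctrl = [], [], [], []
    g_h = brute_censoring_km(time, event, horizon)
    for i in range(n):
        if time[i] <= horizon and event[i] == 1:
            g = brute_censoring_km(time, event, time[i] - 1e-9)
            cases.append(score[i])
            w_case.append(1.0 / g if g > 0 else 0.0)
        elif time[i] > horizon:
            ctrls.append(score[i])
            w_ctrl.append(1.0 / g_h if g_h > 0 else 0.0)
    num = den = 0.0
    for sc, wc in zip(cases, w_case):
        for sn, wn in zip(ctrls, w_ctrl):
            den += wc * wn
            if sc > sn:
                num += wc * wn
            elif sc == sn:
                num += 0.5 * wc * wn
    return num / den


def exact_wilcoxon_p(d):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    stat_obs = abs(w_obs - mu)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= stat_obs - 1e-12:
            count += 1
    return count / 2**n
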