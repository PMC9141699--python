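"""Independent brute-force oracles, coded directly from definitions.

These deliberately share no code with the package: explicit risk sets,
step-by-step running sums, power iteration, exact combinatorics.
"""
from __future__ import annotations

import math

import numpy as np


def efron_score_info_naive(x, time, event, beta=0.0):
    """Cox partial-likelihood score and information at ``beta``, Efron ties,
    via explicit risk-set sums (no sorting tricks)."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    u = 0.0
    info = 0.0
    for t in sorted(set(time[event == 1])):
        deaths = np.nonzero((time == t) & (event == 1))[0]
        risk = np.nonzero(time >= t)[0]
        d = len(deaths)
        w = np.exp(beta * x)
        for ell in range(d):
            frac = ell / d
            denom = w[risk].sum() - frac * w[deaths].sum()
            num = (w[risk] * x[risk]).sum() - frac * (w[deaths] * x[deaths]).sum()
            num2 = (w[risk] * x[risk] ** 2).sum() - frac * (w[deaths] * x[deaths] ** 2).sum()
            u -= num / denom
            info += num2 / denom - (num / denom) ** 2
        u += x[deaths].sum()
    return u, info


def score_z_naive(x, time, event):
    u, info = efron_score_info_naive(x, time, event, beta=0.0)
    if info <= 0:
        return 0.0
    return u / math.sqrt(info)


def logrank_chi2_naive(groups, time, event):
    """Two-group log-rank (O-E)^2/V by explicit per-event-time tabulation."""
    groups = np.asarray(groups, dtype=bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    oe = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & groups).sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        d1 = int((dying & groups).sum())
        oe += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return oe**2 / var


def running_sum_es_naive(metric, in_set, weight=1.0):
    """Step through the ranked list, return the maximum positive deviation."""
    metric = np.asarray(metric, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = len(metric)
    k = int(in_set.sum())
    if n == k:
        return 1.0
    denom = float(np.sum(np.abs(metric[in_set]) ** weight))
    running = 0.0
    best = 0.0
    for i in range(n):
        if in_set[i]:
            if denom > 0:
                running += abs(metric[i]) ** weight / denom
            else:
                running += 1.0 / k
        else:
            running -= 1.0 / (n - k)
        best = max(best, running)
    return best


def power_iteration_weights(abs_corr, n_iter=10_000, tol=1e-14):
    """Dominant eigenvector (non-negative, L1-normalized) of an
    absolute-correlation matrix with the diagonal zeroed, by power iteration."""
    a = np.array(abs_corr, dtype=float, copy=True)
    np.fill_diagonal(a, 0.0)
    p = a.shape[0]
    w = np.full(p, 1.0 / p)
    for _ in range(n_iter):
        nxt = a @ w
        norm = np.abs(nxt).sum()
        if norm == 0:
            return np.full(p, 1.0 / p)
        nxt = nxt / norm
        if np.abs(nxt - w).max() < tol:
            w = nxt
            break
        w = nxt
    w = np.clip(w, 0.0, None)
    return w / w.sum()


def hypergeom_sf_exact(k_obs, n_total, n_success, n_draw):
    """P(X >= k_obs) for a hypergeometric count, exact integer combinatorics."""
    total = math.comb(n_total, n_draw)
    acc = 0
    for k in range(k_obs, min(n_success, n_draw) + 1):
        if n_draw - k > n_total - n_success:
            continue
        acc += math.comb(n_success, k) * math.comb(n_total - n_success, n_draw - k)
    return acc / total


def fixed_effect_pooled_logit(counts, totals):
    """Closed-form inverse-variance pooling of continuity-corrected logit
    proportions (the tau^2 = 0 limit)."""
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    p = (counts + 0.5) / (totals + 1.0)
    y = np.log(p / (1 - p))
    v = 1.0 / (counts + 0.5) + 1.0 / (totals - counts + 0.5)
    w = 1.0 / v
    return float(np.sum(w * y) / np.sum(w))
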