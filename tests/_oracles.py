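"""Independent oracles used by the test suite.

These deliberately avoid the package's closed forms: log-likelihood ratios
are obtained by direct numerical maximization of the model likelihoods, and
ranking metrics by exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def _maximize(nll, x0, bounds=None):
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-13,
                                     "maxiter": 200000, "maxfev": 200000})
    # polish from the NM optimum
    res2 = optimize.minimize(nll, res.x, method="Powell",
                             options={"xtol": 1e-12, "ftol": 1e-14,
                                      "maxiter": 200000})
    return -min(res.fun, res2.fun)


def _cats(E):
    return np.unique(np.asarray(E))


def numeric_llr_correlation(A, B):
    """Bivariate zero-mean normal: alt free rho, null rho = 0."""
    n = len(A)

    def nll(params, rho_free):
        if rho_free:
            la, lb, r = params
        else:
            la, lb = params
            r = 0.0
        sa, sb = np.exp(la), np.exp(lb)
        if abs(r) >= 0.999999:
            return 1e12
        cov = np.array([[sa**2, r * sa * sb], [r * sa * sb, sb**2]])
        return -np.sum(stats.multivariate_normal.logpdf(
            np.column_stack([A, B]), mean=[0, 0], cov=cov))

    ll_alt = _maximize(lambda p: nll(p, True), [0.0, 0.0, 0.1])
    ll_null = _maximize(lambda p: nll(p, False), [0.0, 0.0])
    return ll_alt - ll_null


def numeric_llr_primary(E, A):
    """Alt: genotype-categorical means; null: single free mean/sd."""
    cats = _cats(E)
    idx = np.searchsorted(cats, E)

    def nll_alt(params):
        mus, ls = params[:-1], params[-1]
        return -np.sum(stats.norm.logpdf(A, loc=np.asarray(mus)[idx],
                                         scale=np.exp(ls)))

    def nll_null(params):
        mu, ls = params
        return -np.sum(stats.norm.logpdf(A, loc=mu, scale=np.exp(ls)))

    ll_alt = _maximize(nll_alt, np.concatenate([np.zeros(len(cats)), [0.0]]))
    ll_null = _maximize(nll_null, [0.0, 0.0])
    return ll_alt - ll_null


def numeric_llr_independence(E, A, B):
    cats = _cats(E)
    k = len(cats)
    idx = np.searchsorted(cats, E)
    n = len(A)

    def nll_alt(params):
        mus = np.asarray(params[:k])
        nus = np.asarray(params[k:2 * k])
        la, lb, r = params[2 * k:]
        sa, sb = np.exp(la), np.exp(lb)
        if abs(r) >= 0.999999:
            return 1e12
        ra = (A - mus[idx]) / sa
        rb = (B - nus[idx]) / sb
        quad = (ra**2 - 2 * r * ra * rb + rb**2) / (1 - r**2)
        return 0.5 * np.sum(quad) + n * (np.log(2 * np.pi) + la + lb
                                         + 0.5 * np.log(1 - r**2))

    def nll_null(params):
        mus = np.asarray(params[:k])
        la, r, lb = params[k:]
        sa, sb = np.exp(la), np.exp(lb)
        return (-np.sum(stats.norm.logpdf(A, loc=mus[idx], scale=sa))
                - np.sum(stats.norm.logpdf(B, loc=r * A, scale=sb)))

    ll_alt = _maximize(nll_alt, np.concatenate([np.zeros(2 * k), [0.0, 0.0, 0.1]]))
    ll_null = _maximize(nll_null, np.concatenate([np.zeros(k), [0.0, 0.1, 0.0]]))
    return ll_alt - ll_null


def numeric_llr_relevance(E, A, B):
    """p(A|E) cancels: alt B|E,A with categorical+linear mean; null B free."""
    cats = _cats(E)
    k = len(cats)
    idx = np.searchsorted(cats, E)

    def nll_alt(params):
        nus = np.asarray(params[:k])
        r, ls = params[k:]
        return -np.sum(stats.norm.logpdf(B, loc=nus[idx] + r * A, scale=np.exp(ls)))

    def nll_null(params):
        mu, ls = params
        return -np.sum(stats.norm.logpdf(B, loc=mu, scale=np.exp(ls)))

    ll_alt = _maximize(nll_alt, np.concatenate([np.zeros(k), [0.1, 0.0]]))
    ll_null = _maximize(nll_null, [0.0, 0.0])
    return ll_alt - ll_null


def numeric_llr_controlled(E, A, B):
    """Alt: B|E,A categorical+linear; null: B|E categorical only."""
    cats = _cats(E)
    k = len(cats)
    idx = np.searchsorted(cats, E)

    def nll_alt(params):
        nus = np.asarray(params[:k])
        r, ls = params[k:]
        return -np.sum(stats.norm.logpdf(B, loc=nus[idx] + r * A, scale=np.exp(ls)))

    def nll_null(params):
        nus = np.asarray(params[:k])
        ls = params[k]
        return -np.sum(stats.norm.logpdf(B, loc=nus[idx], scale=np.exp(ls)))

    ll_alt = _maximize(nll_alt, np.concatenate([np.zeros(k), [0.1, 0.0]]))
    ll_null = _maximize(nll_null, np.concatenate([np.zeros(k), [0.0]]))
    return ll_alt - ll_null


def brute_force_auroc(scores, labels):
    """Mean over all (positive, negative) pairs of 1/0.5/0 comparisons."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def exhaustive_aupr(scores, labels, steps_per_unit=2000):
    """Integrate interpolated precision over a fine grid of TP values.

    Between achievable PR points, FP is linear in TP (the Davis-Goadrich
    assumption); precision at fractional TP t is t / (t + FP(t)).  The area
    under precision(recall) is integrated numerically at high resolution.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order].astype(float)
    # achievable points: cumulative (TP, FP) at the end of each tied block
    tp_pts = [0.0]
    fp_pts = [0.0]
    cum_tp, cum_fp = 0.0, 0.0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            cum_tp += y[j]
            cum_fp += 1 - y[j]
            j += 1
        tp_pts.append(cum_tp)
        fp_pts.append(cum_fp)
        i = j
    n_pos = labels.sum()
    area = 0.0
    for a in range(len(tp_pts) - 1):
        dtp = tp_pts[a + 1] - tp_pts[a]
        if dtp <= 0:
            continue
        slope = (fp_pts[a + 1] - fp_pts[a]) / dtp
        m = max(8, int(steps_per_unit * dtp))
        ts = np.linspace(tp_pts[a], tp_pts[a + 1], m + 1)
        fps = fp_pts[a] + slope * (ts - tp_pts[a])
        with np.errstate(invalid="ignore"):
            prec = np.where(ts + fps > 0, ts / (ts + fps), 1.0)
        area += np.trapezoid(prec, ts) / n_pos
    return area
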