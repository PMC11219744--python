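"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test: the dense likelihood
builds the full covariance matrix element by element from the model's
definition and evaluates a multivariate normal directly; percentiles are
computed from sorted order statistics by hand; OLS/GLS come in closed form.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.stats import multivariate_normal


def dense_decay_loglik(t, y, biomarker, participant, session, beta_map,
                       G, tau2, sigma2, phi, ar1="order"):
    """Gaussian log-likelihood of the decay mixed model by brute force.

    ``beta_map``: {biomarker: (intercept, slope)}. ``G``: participant
    random-effect covariance (1x1 or 2x2). Covariance between observations
    i, j: z_i G z_j' if same participant, + tau2 if also same session,
    + sigma2 * phi^d if same (participant, session, biomarker) series, where
    d is the rank distance in time order ("order") or |t_i - t_j|
    ("continuous"); i == j contributes sigma2.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(y)
    G = np.atleast_2d(np.asarray(G, float))
    q = G.shape[0]
    mean = np.array([beta_map[b][0] + beta_map[b][1] * ti
                     for b, ti in zip(biomarker, t)])
    series = [(participant[i], session[i], biomarker[i]) for i in range(n)]
    rank = np.zeros(n)
    for s in set(series):
        idx = [i for i in range(n) if series[i] == s]
        idx.sort(key=lambda i: t[i])
        for r, i in enumerate(idx):
            rank[i] = r
    cov = np.zeros((n, n))
    for i in range(n):
        zi = np.array([1.0, t[i]])[:q]
        for j in range(n):
            zj = np.array([1.0, t[j]])[:q]
            v = 0.0
            if participant[i] == participant[j]:
                v += float(zi @ G @ zj)
                if session[i] == session[j]:
                    v += tau2
            if i == j:
                v += sigma2
            elif series[i] == series[j]:
                d = abs(rank[i] - rank[j]) if ar1 == "order" else abs(t[i] - t[j])
                v += sigma2 * math.copysign(abs(phi) ** d,
                                            1.0 if phi >= 0 or d % 2 == 0 else -1.0)
            cov[i, j] = v
    return float(multivariate_normal(mean=mean, cov=cov,
                                     allow_singular=False).logpdf(y))


def manual_percentile(values, p):
    """Linear interpolation between order statistics, h = (n-1)p + 1."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * p
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def ols_line(t, y):
    """Closed-form least-squares (intercept, slope)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tbar, ybar = t.mean(), y.mean()
    slope = float(((t - tbar) * (y - ybar)).sum() / ((t - tbar) ** 2).sum())
    return ybar - slope * tbar, slope


def gls_beta(X, y, V):
    """Closed-form generalized least squares for a given covariance."""
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    return np.linalg.solve(A, X.T @ Vi @ y)


def pearson_r(x, y):
    """Textbook Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd, yd = x - x.mean(), y - y.mean()
    return float((xd * yd).sum() / math.sqrt((xd ** 2).sum() * (yd ** 2).sum()))
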