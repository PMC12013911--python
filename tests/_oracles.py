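"""Independent oracles used by the test suite.

Each oracle is a deliberately separate implementation of a quantity the
package computes by another route: adaptive Gauss-Hermite quadrature for
the mixed-model marginal likelihood, brute-force enumeration for the
rank-sum null distribution, grid search for the REML between-lab
variance, and a loop-written DerSimonian-Laird formula.  They trade speed
for transparency and are only run on small inputs.
"""
from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, gammaln


def agq_loglik(beta, sigma, X, successes, trials, groups, n_nodes=50):
    """Adaptive Gauss-Hermite marginal log-likelihood for a
    random-intercept binomial-logit model (one scalar intercept per group)."""
    t, w = hermgauss(n_nodes)
    s = np.asarray(successes, float)
    m = np.asarray(trials, float)
    groups = np.asarray(groups)
    eta0 = np.asarray(X, float) @ np.asarray(beta, float)
    const = float(np.sum(gammaln(m + 1) - gammaln(s + 1) - gammaln(m - s + 1)))
    ll = const
    for j in np.unique(groups):
        idx = groups == j
        sj, mj, ej = s[idx], m[idx], eta0[idx]
        u = 0.0
        for _ in range(200):                       # 1-D Newton for the mode
            p = expit(ej + u)
            g = float(np.sum(sj - mj * p)) - u / sigma ** 2
            h = float(np.sum(mj * p * (1 - p))) + 1.0 / sigma ** 2
            u += g / h
            if abs(g / h) < 1e-13:
                break
        c = float(np.sum(mj * expit(ej + u) * (1 - expit(ej + u)))) + 1.0 / sigma ** 2
        sc = np.sqrt(2.0 / c)
        uk = u + sc * t
        hk = np.array([float(np.sum(sj * (ej + uu) - mj * np.logaddexp(0.0, ej + uu)))
                       - uu * uu / (2 * sigma ** 2) for uu in uk])
        hk -= 0.5 * np.log(2 * np.pi * sigma ** 2)
        mx = np.max(hk + t * t)
        ll += np.log(sc) + mx + np.log(np.sum(w * np.exp(hk + t * t - mx)))
    return float(ll)


def fit_agq(X, successes, trials, groups, beta0, sigma0, n_nodes=50):
    """Maximize the AGQ log-likelihood over (beta, log sigma)."""
    def nll(z):
        return -agq_loglik(z[:-1], float(np.exp(z[-1])), X, successes, trials,
                           groups, n_nodes)

    z0 = np.concatenate([beta0, [np.log(max(sigma0, 0.05))]])
    res = minimize(nll, z0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12,
                            "maxiter": 6000, "maxfev": 6000})
    assert res.success, res.message
    return res.x[:-1], float(np.exp(res.x[-1])), -float(res.fun)


def agq_se(X, successes, trials, groups, beta_hat, sigma_hat, n_nodes=50, h=1e-4):
    """Wald SEs from the numeric curvature of the AGQ log-likelihood
    w.r.t. beta at fixed sigma."""
    k = len(beta_hat)
    H = np.zeros((k, k))
    hs = h * np.maximum(1.0, np.abs(beta_hat))

    def f(b):
        return agq_loglik(b, sigma_hat, X, successes, trials, groups, n_nodes)

    for i in range(k):
        for j in range(i, k):
            bpp = np.array(beta_hat); bpp[i] += hs[i]; bpp[j] += hs[j]
            bpm = np.array(beta_hat); bpm[i] += hs[i]; bpm[j] -= hs[j]
            bmp = np.array(beta_hat); bmp[i] -= hs[i]; bmp[j] += hs[j]
            bmm = np.array(beta_hat); bmm[i] -= hs[i]; bmm[j] -= hs[j]
            H[i, j] = H[j, i] = (f(bpp) - f(bpm) - f(bmp) + f(bmm)) / (4 * hs[i] * hs[j])
    return np.sqrt(np.diag(np.linalg.inv(-H)))


def rank_sum_enumeration(a, b):
    """Exact two-sided rank-sum test by enumerating all group assignments.

    Returns (W, p) where W counts pairs with a > b plus half-ties and the
    p-value is the probability, over all equally likely assignments of the
    pooled values to the two groups, of a W at least as far from its null
    mean as the observed one.
    """
    from itertools import combinations

    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na = len(a)

    def w_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    w_obs = w_stat(a, b)
    mean = na * len(b) / 2.0
    stats = []
    for idx in combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        stats.append(w_stat(xs, ys))
    stats = np.array(stats)
    p = float(np.mean(np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12))
    return w_obs, p


def dl_tau2_loops(y, se2):
    """DerSimonian-Laird tau2 written out with explicit loops."""
    k = len(y)
    w = [1.0 / v for v in se2]
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    c = sum(w) - sum(wi ** 2 for wi in w) / sum(w)
    return max(0.0, (q - (k - 1)) / c)


def reml_tau2_grid(y, v, n_grid=10_000, upper=None):
    """REML tau2 by dense grid search over [0, upper]."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if upper is None:
        upper = max(10.0 * float(np.var(y, ddof=1)), 10.0 * float(np.max(v)))
    grid = np.linspace(0.0, upper, n_grid)
    best_t, best_ll = 0.0, -np.inf
    for t2 in grid:
        w = 1.0 / (v + t2)
        mu = np.sum(w * y) / np.sum(w)
        ll = -0.5 * (np.sum(np.log(v + t2)) + np.log(np.sum(w))
                     + np.sum(w * (y - mu) ** 2))
        if ll > best_ll:
            best_t, best_ll = float(t2), float(ll)
    return best_t


def gaussian_lrt_rss(y, x, lab):
    """Closed-form Gaussian interaction LR statistic n*log(RSS_r/RSS_f)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    lab = np.asarray(lab)
    labs = np.unique(lab)
    dummies = (lab[:, None] == labs[None, 1:]).astype(float)
    X_red = np.column_stack([np.ones_like(x), x, dummies])
    X_full = np.column_stack([X_red, dummies * x[:, None]])
    rss = []
    for M in (X_red, X_full):
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
        rss.append(float(np.sum((y - M @ coef) ** 2)))
    return len(y) * np.log(rss[0] / rss[1])
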