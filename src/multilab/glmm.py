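"""Binomial-logit mixed models via the Laplace approximation.

This is the package's numerical core: a random-intercept logistic /
binomial model of the kind used for repeated choice data (one intercept
per individual) and for grouped count data (one intercept per Petri dish
plus an observation-level random effect, OLRE, that absorbs
overdispersion).

Estimation follows the standard two-level scheme:

* inner loop — penalized iteratively reweighted least squares (PIRLS):
  Newton maximization of the penalized log-likelihood over the
  random-effect values for fixed coefficients and variance components.
  Because every random effect is an intercept attached to one grouping
  factor (plus, optionally, one per row nested in that factor), the
  Newton system is solved exactly by block elimination — the
  observation-level block is diagonal and, after eliminating it, the unit
  block is diagonal too.  No large matrix is ever formed.

* outer loop — the Laplace-approximated marginal log-likelihood
  (penalized log-likelihood at the mode minus half the log determinant of
  the random-effects curvature) is maximized over the fixed effects and
  the log-SDs of the variance components by deterministic Nelder-Mead,
  started from a fast profile fit that maximizes the penalized
  log-likelihood jointly over coefficients and random effects (the
  "nAGQ=0"-style shortcut familiar from mixed-model software).

Wald standard errors for the fixed effects come from the inverse Schur
complement of the joint curvature at the optimum, i.e. they condition on
the estimated variance components, matching common mixed-model software
conventions.

A variance component pinned to zero is dropped from the model exactly, so
the fit degenerates to an ordinary logistic/binomial GLM, a property the
test suite exploits.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, gammaln

__all__ = ["BinomialMixedFit", "fit_binomial_glmm", "ConvergenceError", "SeparationError"]

_LOG_2PI = np.log(2.0 * np.pi)
_MAX_ABS_COEF = 25.0


class ConvergenceError(RuntimeError):
    """Raised when the inner or outer optimization fails to converge."""


class SeparationError(ConvergenceError):
    """Raised on (quasi-)complete separation; advise penalized estimation."""


@dataclass
class BinomialMixedFit:
    """Result of a Laplace-approximated binomial mixed-model fit."""

    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    names: list
    loglik: float
    unit_sd: float
    olre_sd: float
    fitted: np.ndarray            # conditional probabilities at the joint mode
    ranef: Optional[np.ndarray]   # unit-level intercept modes
    n_obs: int
    n_groups: int
    n_var_params: int
    converged: bool
    n_outer_evals: int = 0

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.coef) - self.n_var_params

    def pearson_residuals(self, successes: np.ndarray, trials: np.ndarray) -> np.ndarray:
        mu = np.asarray(trials, float) * self.fitted
        v = np.asarray(trials, float) * self.fitted * (1.0 - self.fitted)
        return (np.asarray(successes, float) - mu) / np.sqrt(np.maximum(v, 1e-300))


def _factorize(values) -> tuple:
    """Integer codes for a label array plus the unique labels."""
    uniq, codes = np.unique(np.asarray(values), return_inverse=True)
    return codes, uniq


def _validate(X, successes, trials, groups):
    X = np.asarray(X, dtype=float)
    s = np.asarray(successes, dtype=float)
    m = np.asarray(trials, dtype=float)
    if X.ndim != 2 or len(s) != X.shape[0] or len(m) != X.shape[0]:
        raise ValueError("X, successes and trials must have matching first dimension")
    if np.any(~np.isfinite(s)) or np.any(~np.isfinite(m)):
        raise ValueError("successes and trials must be finite (drop unscorable rows first)")
    if np.any(s < 0) or np.any(s > m) or np.any(m < 1):
        raise ValueError("need 0 <= successes <= trials and trials >= 1 on every row")
    if groups is not None:
        codes, _ = _factorize(groups)
        return X, s, m, codes
    return X, s, m, None


class _Model:
    """Fixed data plus the PIRLS/Laplace machinery, reused across the outer search."""

    def __init__(self, X, s, m, groups, use_unit, use_olre):
        self.X, self.s, self.m = X, s, m
        self.groups = groups
        self.use_unit = bool(use_unit and groups is not None)
        self.use_olre = bool(use_olre)
        self.n, self.p = X.shape
        self.q = int(groups.max()) + 1 if groups is not None else 0
        self.const = float(np.sum(gammaln(m + 1) - gammaln(s + 1) - gammaln(m - s + 1)))
        # warm-start state for the random-effect modes and profile coefficients
        self.beta = np.zeros(self.p)
        self.u = np.zeros(self.q)
        self.e = np.zeros(self.n)

    # -- penalized log-likelihood ------------------------------------------
    def pen_loglik(self, beta, u, e, vu, ve):
        eta = self.X @ beta
        if vu > 0:
            eta = eta + u[self.groups]
        if ve > 0:
            eta = eta + e
        ll = float(np.sum(self.s * eta - self.m * np.logaddexp(0.0, eta))) + self.const
        if vu > 0:
            ll -= 0.5 * float(np.sum(u * u)) / vu + 0.5 * self.q * (np.log(vu) + _LOG_2PI)
        if ve > 0:
            ll -= 0.5 * float(np.sum(e * e)) / ve + 0.5 * self.n * (np.log(ve) + _LOG_2PI)
        return ll, eta

    def _weights(self, eta):
        p_hat = expit(eta)
        return p_hat, self.m * p_hat * (1.0 - p_hat), self.s - self.m * p_hat

    # -- Newton step for the random effects only (beta held fixed) --------
    def _re_step(self, u, e, vu, ve, eta):
        g = self.groups
        _, W, r = self._weights(eta)
        if ve > 0:
            D = W + 1.0 / ve
            g_e = r - e / ve
        if vu > 0:
            if ve > 0:
                Wt = W * (1.0 / ve) / D
                g_u = (np.bincount(g, weights=r, minlength=self.q) - u / vu
                       - np.bincount(g, weights=W / D * g_e, minlength=self.q))
            else:
                Wt = W
                g_u = np.bincount(g, weights=r, minlength=self.q) - u / vu
            A = np.bincount(g, weights=Wt, minlength=self.q) + 1.0 / vu
            d_u = g_u / A
        else:
            d_u = np.zeros(self.q)
        if ve > 0:
            d_e = (g_e - (W * d_u[g] if vu > 0 else 0.0)) / D
        else:
            d_e = np.zeros(self.n)
        return d_u, d_e

    def pirls_re(self, beta, vu, ve, max_iter=100, tol=1e-12):
        """Random-effect modes at fixed beta; returns (u, e, penalized ll, eta)."""
        u = self.u.copy() if vu > 0 else np.zeros(self.q)
        e = self.e.copy() if ve > 0 else np.zeros(self.n)
        ll, eta = self.pen_loglik(beta, u, e, vu, ve)
        if vu <= 0 and ve <= 0:
            return u, e, ll, eta
        for _ in range(max_iter):
            d_u, d_e = self._re_step(u, e, vu, ve, eta)
            step = 1.0
            for _ in range(40):
                nu, ne = u + step * d_u, e + step * d_e
                nll, neta = self.pen_loglik(beta, nu, ne, vu, ve)
                if nll >= ll - 1e-13:
                    break
                step *= 0.5
            else:
                raise ConvergenceError("PIRLS step halving failed (random-effect update)")
            delta = nll - ll
            u, e, ll, eta = nu, ne, nll, neta
            if abs(delta) < tol:
                break
        else:
            raise ConvergenceError("PIRLS over random effects did not converge")
        self.u, self.e = u, e   # warm start for the next outer evaluation
        return u, e, ll, eta

    def logdet_re(self, W, vu, ve):
        """log det of the (unit, OLRE) curvature block at the mode."""
        out = 0.0
        if ve > 0:
            D = W + 1.0 / ve
            out += float(np.sum(np.log(D)))
            Wt = W * (1.0 / ve) / D
        else:
            Wt = W
        if vu > 0:
            A = np.bincount(self.groups, weights=Wt, minlength=self.q) + 1.0 / vu
            out += float(np.sum(np.log(A)))
        return out

    def laplace_loglik(self, beta, vu, ve):
        u, e, ll_pen, eta = self.pirls_re(beta, vu, ve)
        _, W, _ = self._weights(eta)
        n_re = (self.q if vu > 0 else 0) + (self.n if ve > 0 else 0)
        return ll_pen + 0.5 * n_re * _LOG_2PI - 0.5 * self.logdet_re(W, vu, ve)

    # -- joint Newton over (beta, u, e): fast profile used for starts ------
    def profile_step(self, beta, u, e, vu, ve, eta):
        X, g = self.X, self.groups
        _, W, r = self._weights(eta)
        g_b = X.T @ r
        if ve > 0:
            D = W + 1.0 / ve
            g_e = r - e / ve
            Wt = W * (1.0 / ve) / D
            g_bt = g_b - X.T @ (W / D * g_e)
        else:
            Wt, g_bt = W, g_b
        if vu > 0:
            A = np.bincount(g, weights=Wt, minlength=self.q) + 1.0 / vu
            g_u = np.bincount(g, weights=r, minlength=self.q) - u / vu
            if ve > 0:
                g_u = g_u - np.bincount(g, weights=W / D * g_e, minlength=self.q)
            Hbu = np.stack([np.bincount(g, weights=Wt * X[:, k], minlength=self.q)
                            for k in range(self.p)])
            S = (X.T * Wt) @ X - (Hbu / A) @ Hbu.T
            rhs = g_bt - Hbu @ (g_u / A)
        else:
            A = g_u = Hbu = None
            S = (X.T * Wt) @ X
            rhs = g_bt
        d_beta = np.linalg.solve(S, rhs)
        d_u = (g_u - Hbu.T @ d_beta) / A if vu > 0 else np.zeros(self.q)
        if ve > 0:
            d_e = (g_e - W * (X @ d_beta) - (W * d_u[g] if vu > 0 else 0.0)) / D
        else:
            d_e = np.zeros(self.n)
        return d_beta, d_u, d_e, S

    def profile_fit(self, vu, ve, max_iter=200, tol=1e-11):
        """Maximize the penalized log-likelihood jointly over (beta, u, e)."""
        beta, u, e = self.beta.copy(), self.u.copy(), self.e.copy()
        if vu <= 0:
            u = np.zeros(self.q)
        if ve <= 0:
            e = np.zeros(self.n)
        ll, eta = self.pen_loglik(beta, u, e, vu, ve)
        S = None
        for _ in range(max_iter):
            d_beta, d_u, d_e, S = self.profile_step(beta, u, e, vu, ve, eta)
            step = 1.0
            for _ in range(40):
                nb, nu, ne = beta + step * d_beta, u + step * d_u, e + step * d_e
                nll, neta = self.pen_loglik(nb, nu, ne, vu, ve)
                if nll >= ll - 1e-13:
                    break
                step *= 0.5
            else:
                raise ConvergenceError("PIRLS step halving failed (joint update)")
            delta = nll - ll
            beta, u, e, ll, eta = nb, nu, ne, nll, neta
            if abs(delta) < tol:
                break
        else:
            raise ConvergenceError("joint PIRLS did not converge")
        self.beta, self.u, self.e = beta, u, e
        _, W, _ = self._weights(eta)
        n_re = (self.q if vu > 0 else 0) + (self.n if ve > 0 else 0)
        lap = ll + 0.5 * n_re * _LOG_2PI - 0.5 * self.logdet_re(W, vu, ve)
        return beta, u, e, lap, S


def _neg_hessian(fun, x0, rel_step=1e-4):
    """Negative Hessian of a scalar function by central differences."""
    x0 = np.asarray(x0, float)
    k = len(x0)
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h[i] * h[j])
    return -H


def fit_binomial_glmm(
    X: np.ndarray,
    successes: Sequence,
    trials: Sequence,
    groups: Optional[Sequence] = None,
    unit_sd: Optional[float] = None,
    olre: bool = False,
    olre_sd: Optional[float] = None,
    names: Optional[list] = None,
    log_sd_bounds: tuple = (-6.0, 3.0),
) -> BinomialMixedFit:
    """Fit a binomial-logit model with optional random intercepts.

    Parameters
    ----------
    X : (n, p) fixed-effects design matrix.
    successes, trials : per-row counts; pass trials of ones for binary data.
    groups : unit labels for the random intercept, or None for a plain GLM.
    unit_sd : fix the unit SD at this value (0 drops the term); None estimates it.
    olre : include an observation-level random intercept.
    olre_sd : fix the OLRE SD; None estimates it (requires ``olre=True``).
    log_sd_bounds : box for the log-SD coordinates of the outer search; a
        solution at the lower edge is reported as an SD of exactly zero.
    """
    X, s, m, codes = _validate(X, successes, trials, groups)
    use_unit = codes is not None and (unit_sd is None or unit_sd > 0)
    if use_unit and codes.max() == 0:
        raise ValueError("a random intercept requires at least two units")
    if olre_sd is not None and not olre:
        raise ValueError("olre_sd given but olre=False")
    use_olre = olre and (olre_sd is None or olre_sd > 0)

    est_unit = use_unit and unit_sd is None
    est_olre = use_olre and olre_sd is None
    lo, hi = log_sd_bounds
    p = X.shape[1]

    # ---- stage 1: profile fit for starting values ------------------------
    model = _Model(X, s, m, codes, use_unit, use_olre)
    fixed_vu = (unit_sd ** 2 if use_unit else 0.0) if not est_unit else None
    fixed_ve = (olre_sd ** 2 if use_olre else 0.0) if not est_olre else None

    def profile_objective(log_sds):
        k = 0
        vu = float(np.exp(2.0 * np.clip(log_sds[k], lo, hi))) if est_unit else fixed_vu
        k += int(est_unit)
        ve = float(np.exp(2.0 * np.clip(log_sds[k], lo, hi))) if est_olre else fixed_ve
        return -model.profile_fit(vu, ve)[3]

    n_est = int(est_unit) + int(est_olre)
    if n_est == 1:
        res0 = minimize_scalar(lambda t: profile_objective([t]), bounds=(lo, hi),
                               method="bounded", options={"xatol": 1e-4})
        start_sds = [float(res0.x)]
    elif n_est == 2:
        res0 = minimize(profile_objective, x0=np.array([np.log(0.5), np.log(0.5)]),
                        method="Nelder-Mead",
                        options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 300})
        start_sds = [float(v) for v in np.clip(res0.x, lo, hi)]
    else:
        start_sds = []

    # a variance component whose profile estimate sits at the lower edge is
    # a boundary (zero-variance) solution: the Laplace objective is
    # continuous in the SD at 0, so the component is dropped exactly rather
    # than letting the outer search wander on a flat clipped region
    snap = lo + 0.5
    k = 0
    if est_unit:
        if start_sds[k] <= snap:
            return fit_binomial_glmm(X, s, m, groups=groups, unit_sd=0.0,
                                     olre=olre, olre_sd=olre_sd, names=names,
                                     log_sd_bounds=log_sd_bounds)
        k += 1
    if est_olre and start_sds[k] <= snap:
        return fit_binomial_glmm(X, s, m, groups=groups, unit_sd=unit_sd,
                                 olre=olre, olre_sd=0.0, names=names,
                                 log_sd_bounds=log_sd_bounds)

    vu0 = float(np.exp(2.0 * start_sds[0])) if est_unit else fixed_vu
    ve0 = float(np.exp(2.0 * start_sds[int(est_unit)])) if est_olre else fixed_ve
    beta0, _, _, _, _ = model.profile_fit(vu0, ve0)

    def unpack(z):
        beta = z[:p]
        j = p
        if est_unit:
            vu = float(np.exp(2.0 * np.clip(z[j], lo, hi))); j += 1
        else:
            vu = fixed_vu
        if est_olre:
            ve = float(np.exp(2.0 * np.clip(z[j], lo, hi))); j += 1
        else:
            ve = fixed_ve
        return beta, vu, ve

    # ---- stage 2: maximize the Laplace log-likelihood over (beta, log-SDs)
    nfev = 0
    if use_unit or use_olre:
        def objective(z):
            beta, vu, ve = unpack(z)
            # quadratic penalty outside the log-SD box keeps the surface
            # strictly shaped where clipping would make it exactly flat
            excess = z[p:] - np.clip(z[p:], lo, hi)
            return -model.laplace_loglik(beta, vu, ve) + float(np.sum(excess ** 2))

        z0 = np.concatenate([beta0, start_sds])
        # plain (non-adaptive) Nelder-Mead with restarts until the restart
        # no longer improves the log-likelihood
        res = None
        for _ in range(4):
            prev = res
            res = minimize(objective, x0=z0, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-9,
                                    "maxiter": 10000, "maxfev": 10000})
            z0 = res.x
            if prev is not None and prev.fun - res.fun < 1e-8:
                break
        if not res.success:
            raise ConvergenceError(f"Laplace outer optimization failed: {res.message}")
        # a stage-2 boundary solution is likewise snapped to zero variance
        j = p
        if est_unit:
            if res.x[j] <= snap:
                return fit_binomial_glmm(X, s, m, groups=groups, unit_sd=0.0,
                                         olre=olre, olre_sd=olre_sd, names=names,
                                         log_sd_bounds=log_sd_bounds)
            j += 1
        if est_olre and res.x[j] <= snap:
            return fit_binomial_glmm(X, s, m, groups=groups, unit_sd=unit_sd,
                                     olre=olre, olre_sd=0.0, names=names,
                                     log_sd_bounds=log_sd_bounds)
        beta, vu, ve = unpack(res.x)
        loglik = -float(res.fun)
        converged, nfev = bool(res.success), int(res.nfev)
    else:  # plain GLM: joint PIRLS is exact Newton
        beta, _, _, loglik, _ = model.profile_fit(0.0, 0.0)
        vu = ve = 0.0
        converged = True

    if np.max(np.abs(beta)) > _MAX_ABS_COEF:
        raise SeparationError(
            "fixed-effect estimate diverged (likely complete separation); "
            "consider penalized estimation or pooling sparse cells")

    # Wald standard errors: observed information of the marginal (Laplace)
    # log-likelihood w.r.t. beta at fixed variance components.  Central
    # differences; for a plain GLM this equals X'WX so we use that directly.
    u, e, _, eta = model.pirls_re(beta, vu, ve)
    if vu > 0 or ve > 0:
        vcov = np.linalg.inv(_neg_hessian(lambda b: model.laplace_loglik(b, vu, ve), beta))
    else:
        _, _, _, S = model.profile_step(beta, u, e, vu, ve, eta)
        vcov = np.linalg.inv(S)

    # treat a boundary solution (SD at the lower search edge) as zero
    floor = np.exp(lo) * (1.0 + 1e-4)
    sd_u = float(np.sqrt(vu)) if use_unit else 0.0
    sd_e = float(np.sqrt(ve)) if use_olre else 0.0
    if est_unit and sd_u <= floor:
        sd_u = 0.0
    if est_olre and sd_e <= floor:
        sd_e = 0.0
    return BinomialMixedFit(
        coef=beta, se=np.sqrt(np.diag(vcov)), vcov=vcov,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        loglik=float(loglik), unit_sd=sd_u, olre_sd=sd_e,
        fitted=expit(eta), ranef=(u if use_unit else None),
        n_obs=model.n, n_groups=model.q, n_var_params=n_est,
        converged=converged, n_outer_evals=nfev)
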