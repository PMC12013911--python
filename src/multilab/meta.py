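"""Random-effects meta-analysis across laboratories.

Replicate effects y_i with sampling variances v_i are pooled under the
random-effects model y_i ~ N(mu, v_i + tau2), where tau2 is the
between-laboratory variance of true effects.  tau2 is estimated by REML
(default) or the DerSimonian-Laird moment method; the pooled effect is the
inverse-variance weighted mean with weights 1/(v_i + tau2), with Wald-z
confidence interval and p-value (no small-sample adjustment).

``variance_interpretation`` controls how a replicate's reported standard
error enters the pooling:

* ``"se_squared"`` — v_i = SE_i^2, the statistically standard choice for
  new analyses;
* ``"se_as_variance"`` — v_i = SE_i, i.e. the printed SE column is taken
  directly as the sampling variance.  This is the mode that reproduces
  the published overall rows of the multi-laboratory insect study this
  package emulates (all four outcomes match under it and none under
  SE^2), so it is the default for reproducing those numbers.  Reports
  always carry the mode used.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

_Z975 = stats.norm.ppf(0.975)

VARIANCE_INTERPRETATIONS = ("se_squared", "se_as_variance")


@dataclass
class MetaResult:
    """Pooled effect for one outcome across k replicates."""

    outcome_id: str
    mu: float
    se_mu: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float
    q_stat: float
    k: int
    method: str                      # reml | dl | published
    variance_interpretation: str

    @property
    def is_significant(self) -> bool:
        return ci_excludes_zero(self.ci_low, self.ci_high)

    @property
    def sign(self) -> int:
        return int(np.sign(self.mu))


def ci_excludes_zero(ci_low: float, ci_high: float) -> bool:
    """True when the interval lies strictly on one side of zero.

    The comparison is sign-based with IEEE signed zeros honored: a bound
    of −0.0 counts as negative (a negative value rounded to zero when
    printed), while +0.0 counts as touching zero.  On full-precision
    bounds this is the ordinary strict comparison.
    """
    neg = lambda x: x < 0 or (x == 0 and np.signbit(x))
    if neg(ci_low) and neg(ci_high):
        return True
    return ci_low > 0 and ci_high > 0


def _extract(effects, variance_interpretation: str):
    if variance_interpretation not in VARIANCE_INTERPRETATIONS:
        raise ValueError(f"variance_interpretation must be one of {VARIANCE_INTERPRETATIONS}")
    if hasattr(effects[0], "estimate"):
        outcome_ids = {e.outcome_id for e in effects}
        if len(outcome_ids) > 1:
            raise ValueError(f"effects mix outcomes {sorted(outcome_ids)}; pool one outcome at a time")
        outcome = next(iter(outcome_ids))
        y = np.array([e.estimate for e in effects], dtype=float)
        se = np.array([e.se for e in effects], dtype=float)
    else:
        raise TypeError("effects must be a sequence of ReplicateEffect objects")
    v = se if variance_interpretation == "se_as_variance" else se ** 2
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    return outcome, y, v


def cochran_q(y: np.ndarray, v: np.ndarray) -> float:
    """Weighted heterogeneity statistic with fixed-effect weights 1/v."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - mu_fe) ** 2))


def tau2_dl(y: Sequence, v: Sequence) -> float:
    """DerSimonian-Laird moment estimator (closed form, truncated at 0)."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    k = y.size
    if k < 2:
        raise ValueError("need at least two replicates")
    w = 1.0 / v
    c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    return max(0.0, (cochran_q(y, v) - (k - 1)) / c)


def _reml_negll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2))


def tau2_reml(y: Sequence, v: Sequence) -> float:
    """Restricted maximum-likelihood tau2 by bounded 1-D optimization.

    The restricted log-likelihood is maximized on [0, upper] with upper a
    generous multiple of the observed spread; a solution at the lower
    boundary is returned as exactly 0.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if y.size < 2:
        raise ValueError("need at least two replicates")
    upper = max(100.0 * float(np.var(y, ddof=1)) if y.size > 1 else 1.0,
                10.0 * float(np.max(v)), 1e-4)
    res = minimize_scalar(_reml_negll, args=(y, v), bounds=(0.0, upper),
                          method="bounded", options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"REML search failed on [0, {upper:.3g}]: {res.message}")
    t2 = float(res.x)
    # bounded Brent cannot sit exactly on the boundary; snap when the
    # boundary value is at least as good
    if _reml_negll(0.0, y, v) <= res.fun + 1e-12:
        t2 = 0.0
    return t2


def estimate_tau2_dl(effects: Sequence, variance_interpretation: str = "se_squared") -> float:
    """DerSimonian-Laird tau2 from replicate effect objects."""
    _, y, v = _extract(effects, variance_interpretation)
    return tau2_dl(y, v)


def estimate_tau2_reml(effects: Sequence, variance_interpretation: str = "se_squared") -> float:
    """REML tau2 from replicate effect objects."""
    _, y, v = _extract(effects, variance_interpretation)
    return tau2_reml(y, v)


def pool_values(y: Sequence, v: Sequence, method: str = "reml",
                outcome_id: str = "outcome",
                variance_interpretation: str = "se_squared") -> MetaResult:
    """Random-effects pooling of raw (estimate, sampling-variance) pairs."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if y.size < 2:
        raise ValueError("need at least two replicates")
    if method == "reml":
        t2 = tau2_reml(y, v)
    elif method == "dl":
        t2 = tau2_dl(y, v)
    else:
        raise ValueError("method must be 'reml' or 'dl'")
    w = 1.0 / (v + t2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sqrt(1.0 / np.sum(w)))
    z = mu / se_mu
    return MetaResult(outcome_id=outcome_id, mu=mu, se_mu=se_mu,
                      ci_low=mu - _Z975 * se_mu, ci_high=mu + _Z975 * se_mu,
                      p_value=float(2.0 * stats.norm.sf(abs(z))),
                      tau2=t2, q_stat=cochran_q(y, v), k=int(y.size),
                      method=method, variance_interpretation=variance_interpretation)


def pool_random_effects(effects: Sequence, method: str = "reml",
                        variance_interpretation: str = "se_squared") -> MetaResult:
    """Pool one outcome's replicate effects across laboratories."""
    outcome, y, v = _extract(effects, variance_interpretation)
    return pool_values(y, v, method=method, outcome_id=outcome,
                       variance_interpretation=variance_interpretation)
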