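"""Per-replicate effect estimation and auxiliary tests.

One "replicate" is one laboratory's run of one outcome measure.  Its
treatment contrast is estimated on the model scale with the family the
outcome calls for:

* ``gaussian`` — ordinary least squares on the transformed response
  (log(y+1) for immobility durations, sqrt(y) for distances), CI and
  p-value from the t distribution on residual degrees of freedom;
* ``binary_logit`` — logistic regression with an individual-level random
  intercept (Laplace approximation), Wald-z inference;
* ``proportion_logit`` — binomial counts with a dish-level random
  intercept and, optionally, an observation-level random effect (OLRE)
  for overdispersion; Wald-z inference.

Also provided: the Pearson-dispersion overdispersion check, two-sample
rank-sum and Spearman rank-correlation tests, and the pooled
treatment-by-laboratory likelihood-ratio test that asks whether the
treatment effect differs among laboratories.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import OutcomeSpec
from .glmm import BinomialMixedFit, fit_binomial_glmm

_Z975 = stats.norm.ppf(0.975)


@dataclass
class ReplicateEffect:
    """One laboratory's treatment contrast on the model scale."""

    lab_id: str
    outcome_id: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    inference: str                      # t_residual_df | wald_z | degenerate
    n_units: int = 0
    variance_components: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
                raise ValueError("estimate must lie inside its confidence interval")


@dataclass
class TestResult:
    """A named test statistic with its p-value (two-sided throughout)."""

    statistic_name: str                 # W | chi2 | rho | dispersion_ratio
    value: float
    p_value: float
    df: Optional[float] = None
    alternative: str = "two-sided"


# ---------------------------------------------------------------------------
# response transforms
# ---------------------------------------------------------------------------

def transform_response(values: Sequence, transform: str) -> np.ndarray:
    """Apply the outcome's variance-stabilizing transform elementwise.

    ``log1p`` is the natural log of (1 + y), ``sqrt`` the square root,
    ``none`` the identity.  Both transforms require non-negative input.
    """
    values = np.asarray(values, dtype=float)
    if transform == "none":
        return values
    bad = np.flatnonzero(values < 0)
    if bad.size:
        raise ValueError(f"negative response at index {bad[0]} "
                         f"(value {values[bad[0]]!r}) cannot be {transform}-transformed")
    if transform == "log1p":
        return np.log1p(values)
    if transform == "sqrt":
        return np.sqrt(values)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _single_lab(table: pd.DataFrame) -> str:
    labs = table["lab_id"].unique()
    if len(labs) != 1:
        raise ValueError(f"expected a single laboratory, got {sorted(map(str, labs))}; "
                         "use estimate_replicates() for multi-lab tables")
    return str(labs[0])


def _treatment_indicator(table: pd.DataFrame, spec: OutcomeSpec) -> np.ndarray:
    levels = sorted(map(str, table["treatment"].unique()))
    if len(levels) != 2:
        raise ValueError(f"exactly two treatment levels required, got {levels}")
    ref = str(spec.treatment_reference)
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not among treatment levels {levels}")
    return (table["treatment"].astype(str) != ref).to_numpy().astype(float)


def _scorable(table: pd.DataFrame) -> pd.DataFrame:
    if "scorable" in table.columns:
        table = table[table["scorable"].astype(bool)]
    return table


# ---------------------------------------------------------------------------
# per-replicate fits
# ---------------------------------------------------------------------------

def fit_gaussian_model(table: pd.DataFrame, spec: OutcomeSpec) -> ReplicateEffect:
    """Two-group comparison of a transformed continuous response (OLS).

    The contrast is the non-reference minus reference group mean on the
    transformed scale; the CI and p-value use the t distribution with
    n − 2 residual degrees of freedom.  A zero-residual-variance fit
    returns the estimate with degenerate (flagged) inference.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_gaussian_model requires a gaussian outcome spec")
    lab = _single_lab(table)
    table = _scorable(table.dropna(subset=["response"]))
    x = _treatment_indicator(table, spec)
    y = transform_response(table["response"].to_numpy(), spec.transform)
    n0, n1 = int(np.sum(x == 0)), int(np.sum(x == 1))
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 units per treatment level")
    m0, m1 = y[x == 0].mean(), y[x == 1].mean()
    est = m1 - m0
    rss = float(np.sum((y[x == 0] - m0) ** 2) + np.sum((y[x == 1] - m1) ** 2))
    df = n0 + n1 - 2
    s2 = rss / df
    if s2 <= 1e-14:
        return ReplicateEffect(lab, spec.outcome_id, est, 0.0, est, est, np.nan,
                               "degenerate", n_units=n0 + n1)
    se = float(np.sqrt(s2 * (1.0 / n0 + 1.0 / n1)))
    tq = stats.t.ppf(0.975, df)
    p = 2.0 * stats.t.sf(abs(est / se), df)
    return ReplicateEffect(lab, spec.outcome_id, float(est), se,
                           float(est - tq * se), float(est + tq * se), float(p),
                           "t_residual_df", n_units=n0 + n1,
                           variance_components={"residual": s2})


def fit_logistic_mixed_model(table: pd.DataFrame, spec: OutcomeSpec,
                             unit_sd: Optional[float] = None) -> ReplicateEffect:
    """Random-intercept logistic regression for repeated binary choices.

    ``unit_sd`` fixes the individual-intercept SD (0 degenerates to a
    plain logistic GLM); by default it is estimated.
    """
    if spec.family != "binary_logit":
        raise ValueError("fit_logistic_mixed_model requires a binary_logit outcome spec")
    lab = _single_lab(table)
    table = _scorable(table).dropna(subset=["response"])
    if table["unit_id"].nunique() < 2:
        raise ValueError("need at least two individuals with scorable observations")
    x = _treatment_indicator(table, spec)
    y = table["response"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    fit = fit_binomial_glmm(X, y, np.ones_like(y), groups=table["unit_id"].to_numpy(),
                            unit_sd=unit_sd, names=["intercept", "treatment"])
    return _wald_effect(fit, lab, spec, n_units=int(table["unit_id"].nunique()))


def fit_proportion_mixed_model(table: pd.DataFrame, spec: OutcomeSpec,
                               unit_sd: Optional[float] = None,
                               olre_sd: Optional[float] = None) -> ReplicateEffect:
    """Binomial model for per-dish counts with dish (and observation) intercepts.

    Rows carry (successes, trials); rows with zero trials are unscorable
    and dropped.  An OLRE is included when the outcome spec lists it.
    """
    if spec.family != "proportion_logit":
        raise ValueError("fit_proportion_mixed_model requires a proportion_logit outcome spec")
    lab = _single_lab(table)
    table = table.dropna(subset=["successes", "trials"])
    table = table[table["trials"] >= 1]
    if not len(table):
        raise ValueError("all rows have zero trials; nothing to fit")
    x = _treatment_indicator(table, spec)
    X = np.column_stack([np.ones_like(x), x])
    use_olre = "olre" in spec.random_terms
    fit = fit_binomial_glmm(X, table["successes"].to_numpy(float),
                            table["trials"].to_numpy(float),
                            groups=table["unit_id"].to_numpy(),
                            unit_sd=unit_sd, olre=use_olre, olre_sd=olre_sd,
                            names=["intercept", "treatment"])
    return _wald_effect(fit, lab, spec, n_units=int(table["unit_id"].nunique()),
                        olre=use_olre)


def _wald_effect(fit: BinomialMixedFit, lab: str, spec: OutcomeSpec,
                 n_units: int, olre: bool = False) -> ReplicateEffect:
    est, se = float(fit.coef[1]), float(fit.se[1])
    z = est / se
    vc = {}
    if fit.n_groups:
        vc["unit_intercept"] = fit.unit_sd ** 2
    if olre:
        vc["olre"] = fit.olre_sd ** 2
    return ReplicateEffect(lab, spec.outcome_id, est, se,
                           est - _Z975 * se, est + _Z975 * se,
                           float(2.0 * stats.norm.sf(abs(z))), "wald_z",
                           n_units=n_units, variance_components=vc)


_FITTERS = {
    "gaussian": fit_gaussian_model,
    "binary_logit": fit_logistic_mixed_model,
    "proportion_logit": fit_proportion_mixed_model,
}


def fit_replicate(table: pd.DataFrame, spec: OutcomeSpec, **kwargs) -> ReplicateEffect:
    """Fit the family-appropriate model for a single lab × outcome table."""
    return _FITTERS[spec.family](table, spec, **kwargs)


def estimate_replicates(table: pd.DataFrame, spec: OutcomeSpec) -> list:
    """Per-laboratory effects for every lab present in the table."""
    return [fit_replicate(table[table["lab_id"] == lab], spec)
            for lab in sorted(map(str, table["lab_id"].astype(str).unique()))]


# ---------------------------------------------------------------------------
# auxiliary statistics
# ---------------------------------------------------------------------------

def overdispersion_ratio(fit: BinomialMixedFit, successes: Sequence,
                         trials: Sequence) -> TestResult:
    """Pearson dispersion check for a binomial-family fit.

    The ratio is the sum of squared Pearson residuals over the residual
    degrees of freedom; under a correctly specified model it is near 1,
    and the p-value is the upper chi-square tail of the Pearson sum.
    """
    if fit.df_resid <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    r = fit.pearson_residuals(np.asarray(successes, float), np.asarray(trials, float))
    chi2 = float(np.sum(r * r))
    df = fit.df_resid
    return TestResult("dispersion_ratio", chi2 / df, float(stats.chi2.sf(chi2, df)), df=df)


def rank_sum_test(group_a: Sequence, group_b: Sequence) -> TestResult:
    """Two-sample rank-sum test (Mann-Whitney form of the W statistic).

    W counts pairs (a, b) with a > b plus half the ties.  The two-sided
    p-value is exact by enumeration for tie-free samples with combined
    n <= 20, otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if not a.size or not b.size:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and pooled.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult("W", float(res.statistic), float(res.pvalue))


def spearman_correlation(x: Sequence, y: Sequence) -> TestResult:
    """Spearman rank correlation (mid-ranks), two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation is undefined for constant input")
    res = stats.spearmanr(x, y)
    return TestResult("rho", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# pooled treatment-by-laboratory interaction
# ---------------------------------------------------------------------------

def _interaction_designs(table: pd.DataFrame, spec: OutcomeSpec):
    labs = sorted(map(str, table["lab_id"].astype(str).unique()))
    if len(labs) < 2:
        raise ValueError("the interaction test needs at least two laboratories")
    for lab in labs:
        sub = table[table["lab_id"].astype(str) == lab]
        if sub["treatment"].nunique() < 2:
            raise ValueError(f"laboratory {lab!r} has a single treatment level; "
                             "the interaction design is singular")
    x = _treatment_indicator(table, spec)
    lab_codes = table["lab_id"].astype(str).map({l: i for i, l in enumerate(labs)}).to_numpy()
    lab_dummies = np.eye(len(labs))[lab_codes][:, 1:]        # first lab is reference
    n = len(table)
    X_red = np.column_stack([np.ones(n), x, lab_dummies])
    X_full = np.column_stack([X_red, lab_dummies * x[:, None]])
    return labs, x, X_red, X_full


def interaction_lrt(pooled_table: pd.DataFrame, spec: OutcomeSpec) -> TestResult:
    """Likelihood-ratio test of lab-specific treatment effects.

    Compares the pooled model with treatment, laboratory and their
    interaction as fixed effects against the model without the
    interaction; the statistic is twice the log-likelihood difference on
    (number of labs − 1) degrees of freedom.  Gaussian outcomes use the
    closed-form ML statistic n·log(RSS_reduced / RSS_full).
    """
    if spec.family == "gaussian":
        table = _scorable(pooled_table.dropna(subset=["response"]))
        labs, _, X_red, X_full = _interaction_designs(table, spec)
        y = transform_response(table["response"].to_numpy(), spec.transform)
        rss_red = float(np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2))
        rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
        n = len(y)
        chi2 = max(0.0, n * np.log(rss_red / rss_full))
    elif spec.family in ("binary_logit", "proportion_logit"):
        if spec.family == "binary_logit":
            table = _scorable(pooled_table).dropna(subset=["response"])
            s = table["response"].to_numpy(float)
            m = np.ones(len(table))
        else:
            table = pooled_table.dropna(subset=["successes", "trials"])
            table = table[table["trials"] >= 1]
            s = table["successes"].to_numpy(float)
            m = table["trials"].to_numpy(float)
        labs, _, X_red, X_full = _interaction_designs(table, spec)
        groups = table["unit_id"].to_numpy()
        use_olre = "olre" in spec.random_terms
        kw = dict(groups=groups, olre=use_olre)
        ll_full = fit_binomial_glmm(X_full, s, m, **kw).loglik
        ll_red = fit_binomial_glmm(X_red, s, m, **kw).loglik
        chi2 = max(0.0, 2.0 * (ll_full - ll_red))
    else:
        raise ValueError(f"unsupported family {spec.family!r}")
    df = len(labs) - 1
    return TestResult("chi2", float(chi2), float(stats.chi2.sf(chi2, df)), df=df)
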