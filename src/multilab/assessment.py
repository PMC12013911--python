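"""Classification of replicates against the pooled result.

Three criteria, applied per replicate (one laboratory × one outcome):

* significance congruence (the P_sig cell) — the replicate's significance
  status at alpha = 0.05 matches the overall result's status (overall
  significance is decided by whether the pooled 95% CI excludes zero),
  and, when both are significant, the signs agree;
* coverage (the P_cov cell) — the replicate's 95% CI contains the pooled
  point estimate (closed interval: a bound exactly equal to the pooled
  effect counts as covered);
* accuracy (the P_acc cell) — both of the above hold.

Aggregation yields the proportions P_sig, P_cov and P_acc over a chosen
scope: all replicates, one outcome (where the cell fraction counts check
marks over labs × 3 criteria), or the subset of outcomes whose overall
effect is significant.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import ReplicateEffect
from .meta import MetaResult, ci_excludes_zero


@dataclass
class ReplicateAssessment:
    """Per-replicate classification cells."""

    lab_id: str
    outcome_id: str
    replicate_significant: bool
    replicate_sign: int
    overall_significant: bool
    overall_sign: int
    sig_congruent: bool
    covered: bool
    accurate: bool

    def __post_init__(self):
        if self.accurate != (self.sig_congruent and self.covered):
            raise ValueError("accuracy must equal congruence AND coverage")


@dataclass
class ReproducibilitySummary:
    """Aggregate proportions over a set of replicate assessments."""

    scope: str
    n_replicates: int
    sig_count: int
    cov_count: int
    acc_count: int
    grid: pd.DataFrame

    @property
    def p_sig(self) -> float:
        return self.sig_count / self.n_replicates

    @property
    def p_cov(self) -> float:
        return self.cov_count / self.n_replicates

    @property
    def p_acc(self) -> float:
        return self.acc_count / self.n_replicates

    @property
    def cell_fraction(self) -> float:
        return (self.sig_count + self.cov_count + self.acc_count) / (3 * self.n_replicates)


def classify_replicate(rep: ReplicateEffect, overall: MetaResult,
                       alpha: float = 0.05) -> ReplicateAssessment:
    """Apply the three criteria to one replicate against the pooled result.

    Replicate significance uses the replicate's p-value (p < alpha; an
    exact tie at alpha counts as non-significant); overall significance
    uses the pooled CI excluding zero — the two definitions are
    deliberately asymmetric, mirroring how multi-lab replication studies
    state them.  Opposite-sign significance counts as incongruent.
    """
    if rep.outcome_id != overall.outcome_id:
        raise ValueError(f"outcome mismatch: replicate {rep.outcome_id!r} vs "
                         f"overall {overall.outcome_id!r}")
    for name in ("p_value", "ci_low", "ci_high"):
        if not np.isfinite(getattr(rep, name)):
            raise ValueError(f"replicate {rep.lab_id!r} has no usable {name}; "
                             "degenerate fits cannot be classified")
    rep_sig = bool(rep.p_value < alpha)
    rep_sign = int(np.sign(rep.estimate))
    ov_sig = overall.is_significant
    ov_sign = overall.sign
    congruent = rep_sig == ov_sig and (not (rep_sig and ov_sig) or rep_sign == ov_sign)
    covered = bool(rep.ci_low <= overall.mu <= rep.ci_high)
    return ReplicateAssessment(
        lab_id=rep.lab_id, outcome_id=rep.outcome_id,
        replicate_significant=rep_sig, replicate_sign=rep_sign,
        overall_significant=ov_sig, overall_sign=ov_sign,
        sig_congruent=bool(congruent), covered=covered,
        accurate=bool(congruent and covered))


def assessment_grid(assessments: Sequence[ReplicateAssessment]) -> pd.DataFrame:
    """Check-mark matrix: one row per outcome × lab with the three cells."""
    return pd.DataFrame([{
        "outcome_id": a.outcome_id, "lab_id": a.lab_id,
        "sig_congruent": a.sig_congruent, "covered": a.covered,
        "accurate": a.accurate, "overall_significant": a.overall_significant,
    } for a in assessments])


def _summary(assessments: Sequence[ReplicateAssessment], scope: str) -> ReproducibilitySummary:
    n = len(assessments)
    return ReproducibilitySummary(
        scope=scope, n_replicates=n,
        sig_count=sum(a.sig_congruent for a in assessments),
        cov_count=sum(a.covered for a in assessments),
        acc_count=sum(a.accurate for a in assessments),
        grid=assessment_grid(assessments))


def summarize_reproducibility(assessments: Sequence[ReplicateAssessment],
                              scope: str = "total"):
    """Aggregate the classification cells over the requested scope.

    ``"total"`` pools every replicate; ``"per_outcome"`` returns a dict of
    summaries keyed by outcome; ``"per_outcome_group"`` restricts to
    outcomes whose overall effect is significant before pooling (the
    "significant outcomes" subset of replication reports).
    """
    if not assessments:
        raise ValueError("no assessments to summarize")
    if scope == "total":
        return _summary(list(assessments), "total")
    if scope == "per_outcome":
        out = {}
        for outcome in dict.fromkeys(a.outcome_id for a in assessments):
            subset = [a for a in assessments if a.outcome_id == outcome]
            out[outcome] = _summary(subset, "per_outcome")
        return out
    if scope == "per_outcome_group":
        subset = [a for a in assessments if a.overall_significant]
        if not subset:
            raise ValueError("no outcome has a significant overall effect")
        return _summary(subset, "per_outcome_group")
    raise ValueError(f"unknown scope {scope!r}")
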