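"""Reading and writing the pipeline's delimited-text formats.

Observation tables, effects tables and report bundles are UTF-8 CSV with
a header row.  Validation is strict on required columns and value ranges
(e.g. successes <= trials), with errors naming the offending row; unknown
columns only warn so provenance columns can ride along.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .estimation import ReplicateEffect
from .meta import MetaResult

OBS_REQUIRED = ["lab_id", "outcome_id", "unit_id", "treatment"]
EFFECT_COLUMNS = ["lab_id", "outcome_id", "estimate", "se", "ci_low", "ci_high", "p_value"]
OVERALL_COLUMNS = ["outcome_id", "estimate", "se", "ci_low", "ci_high", "p_value"]


def _check_columns(df: pd.DataFrame, required: list, known: list, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}", stacklevel=3)


def read_observations(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a long-format observation table."""
    df = pd.read_csv(path)
    known = OBS_REQUIRED + ["timepoint", "response", "successes", "trials", "scorable"]
    _check_columns(df, OBS_REQUIRED, known, path)
    has_response = "response" in df.columns
    has_counts = "successes" in df.columns and "trials" in df.columns
    if not (has_response or has_counts):
        raise ValueError(f"{path}: need a 'response' column or 'successes'/'trials' columns")
    if has_counts:
        counted = df.dropna(subset=["successes", "trials"])
        bad = counted.index[(counted["successes"] < 0)
                            | (counted["successes"] > counted["trials"])]
        if len(bad):
            raise ValueError(f"{path}: successes > trials (or negative) at row {bad[0] + 2} "
                             "(1-based, counting the header)")
    if "scorable" not in df.columns:
        df["scorable"] = True
    if "timepoint" not in df.columns:
        df["timepoint"] = 0
    key = df[["lab_id", "unit_id", "timepoint"]].astype(str).agg("|".join, axis=1)
    dup = key[key.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate (lab_id, unit_id, timepoint) at row "
                         f"{dup.index[0] + 2}")
    per_unit = df.groupby(["lab_id", "unit_id"])["treatment"].nunique()
    if (per_unit > 1).any():
        lab, unit = per_unit.index[per_unit > 1][0]
        raise ValueError(f"{path}: unit {unit!r} in lab {lab!r} has multiple treatment levels")
    return df


def write_observations(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_effects(path: Union[str, Path]) -> list:
    """Read per-replicate effects (one row per laboratory × outcome)."""
    df = pd.read_csv(path)
    _check_columns(df, EFFECT_COLUMNS, EFFECT_COLUMNS + ["inference", "n_units"], path)
    out = []
    for _, row in df.iterrows():
        out.append(ReplicateEffect(
            lab_id=str(row["lab_id"]), outcome_id=str(row["outcome_id"]),
            estimate=float(row["estimate"]), se=float(row["se"]),
            ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
            p_value=float(row["p_value"]),
            inference=str(row.get("inference", "published")),
            n_units=int(row["n_units"]) if "n_units" in df.columns and pd.notna(row.get("n_units")) else 0))
    return out


def effects_to_frame(effects: Sequence[ReplicateEffect]) -> pd.DataFrame:
    return pd.DataFrame([{
        "lab_id": e.lab_id, "outcome_id": e.outcome_id, "estimate": e.estimate,
        "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high,
        "p_value": e.p_value, "inference": e.inference, "n_units": e.n_units,
        **{f"var_{k}": v for k, v in e.variance_components.items()},
    } for e in effects])


def write_effects(effects: Sequence[ReplicateEffect], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    effects_to_frame(effects).to_csv(path, index=False)
    return path


def read_overall(path: Union[str, Path]) -> dict:
    """Read published pooled rows as MetaResult objects keyed by outcome.

    Float parsing preserves IEEE signed zeros, so a CI bound printed as
    ``-0.00`` keeps its sign and is treated as lying below zero by the
    significance rule.
    """
    df = pd.read_csv(path)
    _check_columns(df, OVERALL_COLUMNS, OVERALL_COLUMNS + ["k", "tau2", "q_stat"], path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["outcome_id"])] = MetaResult(
            outcome_id=str(row["outcome_id"]), mu=float(row["estimate"]),
            se_mu=float(row["se"]), ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]), p_value=float(row["p_value"]),
            tau2=float(row.get("tau2", np.nan)), q_stat=float(row.get("q_stat", np.nan)),
            k=int(row.get("k", 0)) if pd.notna(row.get("k", np.nan)) else 0,
            method="published", variance_interpretation="published")
    return out


def meta_to_frame(results: Sequence[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "outcome_id": r.outcome_id, "mu": r.mu, "se_mu": r.se_mu,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
        "tau2": r.tau2, "q_stat": r.q_stat, "k": r.k, "method": r.method,
        "variance_interpretation": r.variance_interpretation,
        "significant": r.is_significant,
    } for r in results])


def forest_table(effects: Sequence[ReplicateEffect],
                 results: Sequence[MetaResult]) -> pd.DataFrame:
    """Plot-ready rows: per-replicate then pooled, flagged by is_pooled."""
    rows = [{"outcome_id": e.outcome_id, "label": e.lab_id, "estimate": e.estimate,
             "ci_low": e.ci_low, "ci_high": e.ci_high, "is_pooled": False}
            for e in effects]
    rows += [{"outcome_id": r.outcome_id, "label": "overall", "estimate": r.mu,
              "ci_low": r.ci_low, "ci_high": r.ci_high, "is_pooled": True}
             for r in results]
    return pd.DataFrame(rows)


def write_json(obj, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
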