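"""End-to-end orchestration: simulate → estimate → pool → classify → report.

A run is fully determined by a :class:`~multilab.config.PipelineConfig`
plus its seed.  Three entry routes exist:

* a simulation scenario (generates observations first);
* an observation file (starts at estimation);
* an effects file of precomputed per-replicate estimates (skips straight
  to pooling and classification — the canonical route for reproducing a
  published summary table; the sentinel path ``"published"`` loads the
  bundled three-lab insect study effects).

Outputs are plain CSV/JSON/YAML tables mirroring the effect-size and
check-mark tables of multi-laboratory replication reports, plus a run
manifest with a config hash so identical runs are identifiable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .assessment import classify_replicate, summarize_reproducibility
from .config import OutcomeSpec, PipelineConfig, SimulationConfig
from .datasets import load_published_effects
from .estimation import estimate_replicates, interaction_lrt
from .io import (effects_to_frame, forest_table, meta_to_frame, read_effects,
                 read_observations, write_json)
from .meta import pool_random_effects
from .simulate import simulate

logger = logging.getLogger("multilab")

ARCHETYPE_SPECS = {
    "gaussian_two_group": dict(family="gaussian", random_terms=()),
    "binary_repeated_choice": dict(family="binary_logit", random_terms=("unit_intercept",)),
    "dish_proportion": dict(family="proportion_logit", random_terms=("unit_intercept", "olre")),
}


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage, partial outputs remain."""


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    effects: pd.DataFrame
    meta: pd.DataFrame
    grid: pd.DataFrame
    summary: dict
    manifest: dict
    interaction: Optional[pd.DataFrame] = None
    observations: Optional[pd.DataFrame] = None


def spec_for_scenario(config: SimulationConfig) -> OutcomeSpec:
    """Analysis spec matching a simulation archetype's generative model."""
    base = ARCHETYPE_SPECS[config.archetype]
    return OutcomeSpec(outcome_id=config.outcome_id, transform=config.transform,
                       treatment_reference=str(config.treatment_levels[0]), **base)


def _load_effects(source) -> list:
    if source == "published":
        return load_published_effects()
    return read_effects(source)


def _summaries(assessments) -> dict:
    total = summarize_reproducibility(assessments, "total")
    per_outcome = summarize_reproducibility(assessments, "per_outcome")
    out = {
        "total": _summary_dict(total),
        "per_outcome": {k: _summary_dict(v) for k, v in per_outcome.items()},
    }
    try:
        out["significant_outcomes"] = _summary_dict(
            summarize_reproducibility(assessments, "per_outcome_group"))
    except ValueError:
        out["significant_outcomes"] = None
    return out


def _summary_dict(s) -> dict:
    return {"n_replicates": s.n_replicates,
            "p_sig": s.p_sig, "p_cov": s.p_cov, "p_acc": s.p_acc,
            "sig_count": s.sig_count, "cov_count": s.cov_count,
            "acc_count": s.acc_count, "cell_fraction": s.cell_fraction}


def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[Union[str, Path]] = None) -> ReportBundle:
    """Execute all stages of a configured run; optionally write as you go."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("run starts: seed=%d hash=%s", config.seed, config.config_hash())
    writer = _StageWriter(Path(out_dir)) if out_dir is not None else None
    observations = None
    interaction_rows = []

    stage = "input"
    try:
        if config.scenario is not None:
            stage = "simulate"
            sim = (SimulationConfig.from_yaml(config.scenario)
                   if isinstance(config.scenario, (str, Path))
                   else SimulationConfig.from_dict(dict(config.scenario)))
            sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
            observations = simulate(sim)
            specs = {sim.outcome_id: spec_for_scenario(sim)}
            if writer:
                writer.csv("observations.csv", observations)
        elif config.observations is not None:
            stage = "read_observations"
            observations = read_observations(config.observations)
            specs = config.outcome_specs()
            missing = set(observations["outcome_id"].astype(str)) - set(specs)
            if missing:
                raise ValueError(f"no outcome spec for {sorted(missing)}")
        else:
            specs = config.outcome_specs()

        if observations is not None:
            stage = "estimate"
            effects = []
            for outcome_id, spec in specs.items():
                sub = observations[observations["outcome_id"].astype(str) == outcome_id]
                reps = estimate_replicates(sub, spec)
                for r in reps:
                    logger.info("fit %s/%s: est=%.4f se=%.4f vc=%s",
                                r.lab_id, outcome_id, r.estimate, r.se,
                                r.variance_components)
                effects.extend(reps)
                if sub["lab_id"].nunique() >= 2:
                    t = interaction_lrt(sub, spec)
                    interaction_rows.append({
                        "outcome_id": outcome_id, "chi2": t.value,
                        "df": t.df, "p_value": t.p_value})
        else:
            stage = "read_effects"
            effects = _load_effects(config.effects)
        if writer:
            writer.csv("effects.csv", effects_to_frame(effects))

        stage = "meta"
        results = []
        by_outcome = {}
        for e in effects:
            by_outcome.setdefault(e.outcome_id, []).append(e)
        for outcome_id, reps in by_outcome.items():
            if len(reps) < 2:
                logger.warning("outcome %s has a single replicate; skipping pooling", outcome_id)
                continue
            results.append(pool_random_effects(
                reps, method=config.meta_method,
                variance_interpretation=config.variance_interpretation))
        if not results:
            raise ValueError("no outcome had >= 2 replicates to pool")
        if writer:
            writer.csv("meta.csv", meta_to_frame(results))
            writer.csv("forest.csv", forest_table(effects, results))

        stage = "assess"
        overall = {r.outcome_id: r for r in results}
        assessments = [classify_replicate(e, overall[e.outcome_id], alpha=config.alpha)
                       for e in effects if e.outcome_id in overall]
        grid = summarize_reproducibility(assessments, "total").grid
        summary = _summaries(assessments)

        stage = "report"
        manifest = {
            "config": config.to_dict(), "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": _versions(),
        }
        interaction = pd.DataFrame(interaction_rows) if interaction_rows else None
        bundle = ReportBundle(effects=effects_to_frame(effects),
                              meta=meta_to_frame(results), grid=grid,
                              summary=summary, manifest=manifest,
                              interaction=interaction, observations=observations)
        if writer:
            writer.csv("grid.csv", grid)
            if interaction is not None:
                writer.csv("interaction.csv", interaction)
            writer.json("summary.json", summary)
            writer.yaml("manifest.yaml", manifest)
        logger.info("run complete: %d effects, %d pooled outcomes", len(effects), len(results))
        return bundle
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def write_report(bundle: ReportBundle, out_dir: Union[str, Path]) -> dict:
    """Write every table of a bundle; returns name → path."""
    w = _StageWriter(Path(out_dir))
    paths = {
        "effects": w.csv("effects.csv", bundle.effects),
        "meta": w.csv("meta.csv", bundle.meta),
        "grid": w.csv("grid.csv", bundle.grid),
        "summary": w.json("summary.json", bundle.summary),
        "manifest": w.yaml("manifest.yaml", bundle.manifest),
    }
    if bundle.interaction is not None:
        paths["interaction"] = w.csv("interaction.csv", bundle.interaction)
    if bundle.observations is not None:
        paths["observations"] = w.csv("observations.csv", bundle.observations)
    return paths


class _StageWriter:
    def __init__(self, out_dir: Path):
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)

    def csv(self, name: str, df: pd.DataFrame) -> Path:
        p = self.dir / name
        df.to_csv(p, index=False)
        return p

    def json(self, name: str, obj) -> Path:
        return write_json(obj, self.dir / name)

    def yaml(self, name: str, obj) -> Path:
        p = self.dir / name
        with open(p, "w") as fh:
            yaml.safe_dump(obj, fh, sort_keys=False)
        return p


def _versions() -> dict:
    import numpy
    import scipy
    return {"multilab": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
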