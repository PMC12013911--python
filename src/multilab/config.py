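"""Configuration objects for simulation, estimation, and pipeline runs.

Configuration is kept declarative: every knob of the data-generating process
and of the analysis lives in a plain dataclass that round-trips through YAML,
so a scenario file fully determines a run (together with the seed).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

ARCHETYPES = ("gaussian_two_group", "binary_repeated_choice", "dish_proportion")
FAMILIES = ("gaussian", "binary_logit", "proportion_logit")
TRANSFORMS = ("log1p", "sqrt", "none")


@dataclass
class SimulationConfig:
    """Full specification of a synthetic multi-laboratory experiment.

    Parameters are on the model (link) scale: ``beta`` is the treatment
    contrast on the transformed scale for the gaussian archetype and a
    log-odds contrast otherwise.  ``lab_intercept_sd`` shifts whole
    laboratories; ``lab_slope_sd`` draws lab-specific deviations of the
    treatment effect and is what creates a treatment-by-laboratory
    interaction.  ``availability_prob`` thins observations to mimic
    unscorable records (animal off the floor / on its back); it may be a
    single probability or a ``{treatment_level: prob}`` mapping.
    """

    archetype: str
    n_labs: int = 3
    units_per_group_per_lab: int = 30
    alpha: float = 0.0
    beta: float = 0.0
    lab_intercept_sd: float = 0.0
    lab_slope_sd: float = 0.0
    unit_re_sd: float = 0.0
    olre_sd: float = 0.0
    residual_sd: float = 1.0
    n_timepoints: int = 1
    availability_prob: Union[float, dict] = 1.0
    response_ceiling: Optional[float] = None
    transform: str = "none"
    group_size: int = 3
    treatment_levels: tuple = ("control", "treated")
    outcome_id: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}")
        for name in ("lab_intercept_sd", "lab_slope_sd", "unit_re_sd", "olre_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_labs", "units_per_group_per_lab", "n_timepoints", "group_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for level, p in self.availability_by_level().items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"availability_prob for {level!r} must be in (0, 1], got {p}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.archetype == "gaussian_two_group":
            if self.residual_sd <= 0:
                raise ValueError("residual_sd must be > 0 for the gaussian archetype")
            if self.response_ceiling is not None and self.response_ceiling < 0:
                raise ValueError("response_ceiling must be non-negative on the raw scale")
        if len(self.treatment_levels) != 2:
            raise ValueError("exactly two treatment levels are required")
        self.treatment_levels = tuple(self.treatment_levels)

    def availability_by_level(self) -> dict:
        """Availability probability resolved per treatment level."""
        if isinstance(self.availability_prob, dict):
            out = {}
            for level in self.treatment_levels:
                out[str(level)] = float(self.availability_prob.get(str(level), 1.0))
            return out
        return {str(level): float(self.availability_prob) for level in self.treatment_levels}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatment_levels"] = list(self.treatment_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "treatment_levels" in d:
            d["treatment_levels"] = tuple(d["treatment_levels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class OutcomeSpec:
    """Analysis contract for one outcome measure.

    ``family`` selects the per-replicate model (plain gaussian linear model,
    random-intercept logistic, or binomial proportion model with unit and
    observation-level random intercepts); ``transform`` is applied to the
    raw response before a gaussian fit.  The treatment contrast is always
    non-reference level minus ``treatment_reference`` on the model scale.
    """

    outcome_id: str
    family: str
    transform: str = "none"
    random_terms: tuple = ()
    treatment_reference: str = "control"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        self.random_terms = tuple(self.random_terms)
        for term in self.random_terms:
            if term not in ("unit_intercept", "olre"):
                raise ValueError(f"unknown random term {term!r}")
        if "olre" in self.random_terms and self.family != "proportion_logit":
            raise ValueError("an observation-level random effect is only supported with proportion_logit")
        if self.transform != "none" and self.family != "gaussian":
            raise ValueError("transforms only apply to gaussian responses")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["random_terms"] = list(self.random_terms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeSpec":
        d = dict(d)
        if "random_terms" in d:
            d["random_terms"] = tuple(d["random_terms"])
        return cls(**d)


@dataclass
class PipelineConfig:
    """Declarative end-to-end run: one input source, per-outcome specs, options.

    Exactly one of ``observations``, ``effects`` or ``scenario`` must be set.
    When ``effects`` is given (a file of precomputed per-replicate estimates)
    the estimation stage is skipped and pooling/classification run directly —
    this is the route for reproducing published summary tables.
    """

    observations: Optional[str] = None
    effects: Optional[str] = None
    scenario: Optional[Union[str, dict]] = None
    outcomes: dict = field(default_factory=dict)  # outcome_id -> OutcomeSpec dict
    meta_method: str = "reml"
    variance_interpretation: str = "se_squared"
    alpha: float = 0.05
    output_dir: str = "multilab_output"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.observations, self.effects, self.scenario)]
        if sum(sources) != 1:
            raise ValueError("exactly one input source (observations | effects | scenario) is required")
        if self.meta_method not in ("reml", "dl"):
            raise ValueError("meta_method must be 'reml' or 'dl'")
        if self.variance_interpretation not in ("se_squared", "se_as_variance"):
            raise ValueError("variance_interpretation must be 'se_squared' or 'se_as_variance'")

    def outcome_specs(self) -> dict:
        return {k: OutcomeSpec.from_dict({"outcome_id": k, **v}) if not isinstance(v, OutcomeSpec) else v
                for k, v in self.outcomes.items()}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcomes"] = {k: (v.to_dict() if isinstance(v, OutcomeSpec) else dict(v))
                         for k, v in self.outcomes.items()}
        return d

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable digest over semantically meaningful fields (excludes log level)."""
        d = self.to_dict()
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
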