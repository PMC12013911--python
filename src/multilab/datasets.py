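"""Bundled summary data from a three-laboratory insect replication study.

The package ships the per-laboratory treatment-effect estimates (with
standard errors, 95% CIs and p-values) and the published pooled rows for
the study's four outcome measures, typed from the published summary
table:

* ``pci_duration`` — starvation contrast for sawfly post-contact
  immobility, log(s+1) scale;
* ``distance_moved`` — starvation contrast for sawfly activity,
  sqrt(cm) scale;
* ``substrate_choice`` — grasshopper color-morph contrast for green-patch
  preference, log-odds;
* ``niche_choice`` — flour-beetle life-stage contrast for quinone-reduced
  flour preference, log-odds.

p-values reported only as "< 0.001" are stored as 0.001 (an upper bound;
every consumer only compares against alpha = 0.05).  The niche-choice
pooled CI bound printed as "−0.00" is stored with its sign so the
significance rule can honor "negative before rounding".
"""
from __future__ import annotations

from importlib import resources

from . import io

SIGNIFICANT_OUTCOMES = ("pci_duration", "distance_moved", "niche_choice")


def _data_path(name: str):
    return resources.files("multilab").joinpath("data", name)


def load_published_effects() -> list:
    """Per-lab replicate effects (12 rows: 3 labs × 4 outcomes)."""
    with resources.as_file(_data_path("published_effects.csv")) as p:
        return io.read_effects(p)


def load_published_overall() -> dict:
    """Published pooled rows keyed by outcome (4 entries)."""
    with resources.as_file(_data_path("published_overall.csv")) as p:
        return io.read_overall(p)
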