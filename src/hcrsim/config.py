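"""Scenario configuration files (YAML or JSON).

A scenario block names the life history and catch history and carries the
projection settings, e.g.::

    life_history: medium
    catch_history: fully
    catch_noise_sd: 0.1
    hist_years: 10
    last_hist_year: 2019
    proj_years: 30
    n_replicates: 250
    seed: 42
    bio_sd: 0.2
    bio_rho: 0.5
    est_sd: 0.0
    est_bias: 0.0

Every key is optional; omitted keys take the defaults above.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .operating_model import CatchHistoryScenario, LifeHistory, make_life_history
from .projection import ProjectionConfig

__all__ = ["load_scenario", "scenario_from_dict"]


def scenario_from_dict(doc: dict) -> tuple[LifeHistory, CatchHistoryScenario, ProjectionConfig]:
    doc = dict(doc or {})
    lh = make_life_history(doc.pop("life_history", "medium"))
    scenario = CatchHistoryScenario(
        label=doc.pop("catch_history", "fully"),
        noise_sd=float(doc.pop("catch_noise_sd", 0.1)),
    )
    cfg = ProjectionConfig.from_dict(doc)
    return lh, scenario, cfg


def load_scenario(path: str | Path) -> tuple[LifeHistory, CatchHistoryScenario, ProjectionConfig]:
    """Read a scenario file; YAML is a superset of JSON so both parse."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    return scenario_from_dict(doc)
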