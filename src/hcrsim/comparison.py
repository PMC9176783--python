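"""Basket evaluation: compare candidate rules under one scenario.

Every rule in a basket is projected under the same life history, catch
history and projection settings.  By default the rules share the master
seed, so each replicate sees identical noise sequences under every rule
(common random numbers) — differences between rules are then differences
in the rules, not in the Monte-Carlo draw.  Independent seeding per rule
is available for sensitivity checks.

The report can be thinned by dropping indicators or rules; what was
dropped is recorded in the report's provenance so a filtered table is
never mistaken for a complete one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .harvest_rules import HarvestRule
from .indicators import (
    INDICATOR_NAMES,
    PeriodDefinition,
    ReferencePoints,
    StabilityParams,
    indicator_table,
)
from .operating_model import CatchHistoryScenario, LifeHistory
from .projection import ProjectionConfig, ReplicateSet, run_replicates

__all__ = ["Basket", "ComparisonReport", "evaluate_basket", "filter_report"]


@dataclass(frozen=True)
class Basket:
    """Named candidate rules plus the shared scenario and settings."""

    rules: tuple[HarvestRule, ...]
    lh: LifeHistory
    scenario: CatchHistoryScenario
    cfg: ProjectionConfig

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("a basket needs at least one rule")
        names = [r.name for r in self.rules]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate rule names in basket: {sorted(dupes)}")


@dataclass(frozen=True)
class ComparisonReport:
    """Indicator table over all rules plus provenance of how it was made."""

    table: pd.DataFrame
    provenance: dict
    dropped_indicators: tuple[str, ...] = ()
    dropped_rules: tuple[str, ...] = ()

    @property
    def rule_names(self) -> tuple[str, ...]:
        return tuple(self.table["rule"].unique())

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(self.table["indicator"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _independent_seed(master: int, index: int) -> int:
    # derived deterministically from the master seed; kept below 2**31
    ss = np.random.SeedSequence([master, index + 1])
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_basket(
    basket: Basket,
    rp: ReferencePoints = ReferencePoints(),
    periods: PeriodDefinition | None = None,
    independent_seeds: bool = False,
    keep_trajectories: bool = False,
) -> ComparisonReport:
    """Project every rule in the basket and assemble the indicator table.

    Deterministic given the basket's seed.  With ``independent_seeds``
    each rule gets its own seed derived from the master, instead of the
    default common-random-number pairing.
    """
    sp = StabilityParams.from_life_history(basket.lh)
    tables = []
    cap_fracs: dict[str, float] = {}
    trajectories: dict[str, ReplicateSet] = {}
    for i, rule in enumerate(basket.rules):
        cfg = basket.cfg
        if independent_seeds:
            cfg = replace(cfg, seed=_independent_seed(cfg.seed, i))
        reps = run_replicates(basket.lh, basket.scenario, rule, cfg)
        tables.append(indicator_table(reps, rp=rp, sp=sp, periods=periods))
        cap_fracs[rule.name] = reps.cap_binding_fraction
        if keep_trajectories:
            trajectories[rule.name] = reps
    provenance = {
        "version": __version__,
        "seed": basket.cfg.seed,
        "independent_seeds": independent_seeds,
        "life_history": basket.lh.label,
        "catch_history": basket.scenario.label,
        "config": basket.cfg.to_dict(),
        "reference_points": {"lrp": rp.lrp, "trp": rp.trp},
        "cvar_max": sp.cvar_max,
        "rules": [r.to_dict() for r in basket.rules],
        "cap_binding_fraction": cap_fracs,
        "dropped_indicators": [],
        "dropped_rules": [],
    }
    report = ComparisonReport(table=pd.concat(tables, ignore_index=True), provenance=provenance)
    if keep_trajectories:
        object.__setattr__(report, "_trajectories", trajectories)
    return report


def filter_report(
    report: ComparisonReport,
    drop_indicators: Sequence[str] = (),
    drop_rules: Sequence[str] = (),
) -> ComparisonReport:
    """Return a reduced report with the named rows removed.

    The original report is untouched; the provenance of the new report
    records everything dropped so far.  Dropping an unknown name, or every
    remaining rule, is an error.
    """
    for ind in drop_indicators:
        if ind not in report.indicator_names:
            raise ValueError(f"unknown indicator {ind!r}; have {report.indicator_names}")
    for rule in drop_rules:
        if rule not in report.rule_names:
            raise ValueError(f"unknown rule {rule!r}; have {report.rule_names}")
    remaining_rules = [r for r in report.rule_names if r not in set(drop_rules)]
    if not remaining_rules:
        raise ValueError("cannot drop every rule from a report")
    table = report.table[
        ~report.table["indicator"].isin(set(drop_indicators))
        & ~report.table["rule"].isin(set(drop_rules))
    ].reset_index(drop=True)
    dropped_ind = report.dropped_indicators + tuple(drop_indicators)
    dropped_rules = report.dropped_rules + tuple(drop_rules)
    provenance = dict(report.provenance)
    provenance["dropped_indicators"] = list(dropped_ind)
    provenance["dropped_rules"] = list(dropped_rules)
    return ComparisonReport(
        table=table,
        provenance=provenance,
        dropped_indicators=dropped_ind,
        dropped_rules=dropped_rules,
    )
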