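"""Performance indicators and their period summaries.

Seven indicators are computed over the projection years of a replicate
set, following the standard comparison table:

====================  =========================================================
biomass               true relative biomass B/K (not the estimate the rule saw)
prob_above_lrp        per-year fraction of replicates with B/K above the LRP
catch                 realised catch
relative_cpue         CPUE scaled by the last historical year's CPUE
relative_effort       effort scaled by the last historical year's effort
catch_stability       1 - |C_y - C_{y-1}| / Cvar_max, clamped to [0, 1]
trp_proximity         1 - |B/K - TRP| / max(TRP, 1-TRP), clamped to [0, 1]
====================  =========================================================

Reference points: the limit reference point (LRP, default 0.2 relative
biomass) bounds acceptable risk; the target reference point (TRP, default
0.5) is the desired operating level.  Cvar_max defaults to K/10.

Each indicator is averaged per replicate over three contiguous time
periods (short / medium / long term) and summarised across replicates as
the median with the 90th (5th-95th) and 80th (10th-90th) percentile
ranges, linear-interpolation quantiles.  The probability-above-LRP row is
already a cross-replicate quantity, so it is period-averaged and reported
without percentile bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .operating_model import LifeHistory
from .projection import ReplicateSet

__all__ = [
    "ReferencePoints",
    "StabilityParams",
    "PeriodDefinition",
    "prob_above_lrp",
    "catch_stability",
    "trp_proximity",
    "effort_and_cpue",
    "summarise",
    "indicator_table",
    "indicator_table_from_frame",
    "INDICATOR_NAMES",
]

INDICATOR_NAMES = (
    "biomass",
    "prob_above_lrp",
    "catch",
    "relative_cpue",
    "relative_effort",
    "catch_stability",
    "trp_proximity",
)

TABLE_COLUMNS = ["rule", "indicator", "period", "median", "lo90", "hi90", "lo80", "hi80"]


@dataclass(frozen=True)
class ReferencePoints:
    """Limit and target biomass reference points (relative biomass)."""

    lrp: float = 0.2
    trp: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.lrp < self.trp < 1:
            raise ValueError("need 0 < lrp < trp < 1")


@dataclass(frozen=True)
class StabilityParams:
    """Maximum expected catch variability used to scale catch stability."""

    cvar_max: float

    def __post_init__(self) -> None:
        if not self.cvar_max > 0:
            raise ValueError("cvar_max must be positive")

    @classmethod
    def from_life_history(cls, lh: LifeHistory) -> "StabilityParams":
        return cls(cvar_max=lh.K / 10.0)


@dataclass(frozen=True)
class PeriodDefinition:
    """Three contiguous projection-year windows: short, medium, long term."""

    short: tuple[int, ...]
    medium: tuple[int, ...]
    long: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (self.short and self.medium and self.long):
            raise ValueError("every period must contain at least one year")
        seq = self.short + self.medium + self.long
        if list(seq) != sorted(set(seq)):
            raise ValueError("periods must be disjoint, ordered and contiguous")

    def items(self) -> list[tuple[str, tuple[int, ...]]]:
        return [("short", self.short), ("medium", self.medium), ("long", self.long)]

    @classmethod
    def equal_thirds(cls, years: Sequence[int]) -> "PeriodDefinition":
        """Split the projection years into three equal contiguous windows.

        Remainder years (when the count is not divisible by 3) go to the
        long-term window.
        """
        years = tuple(int(y) for y in years)
        if len(years) < 3:
            raise ValueError("need at least 3 projection years to define periods")
        n = len(years) // 3
        return cls(short=years[:n], medium=years[n : 2 * n], long=years[2 * n :])


def prob_above_lrp(biomass_rel, rp: ReferencePoints = ReferencePoints()) -> np.ndarray:
    """Per-year fraction of replicates strictly above the LRP.

    ``biomass_rel`` is a replicates x years array (or DataFrame) of true
    relative biomass.
    """
    mat = np.atleast_2d(np.asarray(biomass_rel, dtype=float))
    if mat.shape[0] < 1:
        raise ValueError("need at least one replicate")
    return (mat > rp.lrp).mean(axis=0)


def catch_stability(catch, sp: StabilityParams) -> np.ndarray:
    """Per-year catch stability, defined from the second year of the series.

    Cvar_y = |C_y - C_{y-1}|; Cstab_y = clamp(1 - Cvar_y / Cvar_max, 0, 1).
    1 means the catches did not change at all; 0 means the year-on-year
    change reached (or exceeded) Cvar_max.  Works on a 1-D series or a
    replicates x years matrix (returns one fewer column).
    """
    arr = np.asarray(catch, dtype=float)
    if arr.shape[-1] < 2:
        raise ValueError("catch stability needs a series of at least 2 years")
    cvar = np.abs(np.diff(arr, axis=-1))
    return np.clip(1.0 - cvar / sp.cvar_max, 0.0, 1.0)


def trp_proximity(biomass_rel, rp: ReferencePoints = ReferencePoints()) -> np.ndarray:
    """Proximity of relative biomass to the TRP, scaled to [0, 1].

    1 - |B - TRP| / max(TRP, 1 - TRP), clamped below at 0.  Symmetric: it
    does not distinguish biomass above the TRP from biomass below it.
    """
    arr = np.asarray(biomass_rel, dtype=float)
    if np.any(arr < 0):
        raise ValueError("relative biomass must be non-negative")
    max_dist = max(rp.trp, 1.0 - rp.trp)
    return np.clip(1.0 - np.abs(arr - rp.trp) / max_dist, 0.0, 1.0)


def effort_and_cpue(catch, biomass, q: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Fishing effort E = C/(B*q) and CPUE = C/E = B*q.

    Zero catch gives zero effort; CPUE uses the closed form B*q, which is
    defined for every year.  Zero biomass with positive catch is an error.
    """
    c = np.asarray(catch, dtype=float)
    b = np.asarray(biomass, dtype=float)
    if np.any((b <= 0) & (c > 0)):
        raise ValueError("positive catch requires positive biomass")
    effort = np.divide(c, b * q, out=np.zeros_like(c), where=b > 0)
    return effort, b * q


def summarise(
    values: pd.DataFrame,
    periods: PeriodDefinition,
    percentiles: Sequence[float] = (5, 95, 10, 90),
) -> pd.DataFrame:
    """Period-average per replicate, then take cross-replicate quantiles.

    ``values`` is a replicates x years DataFrame (columns are year
    labels).  For each period the yearly values are averaged within each
    replicate; the median and the requested percentiles of those
    per-replicate means are reported.
    """
    lo90, hi90, lo80, hi80 = percentiles
    rows = []
    for label, years in periods.items():
        missing = [y for y in years if y not in values.columns]
        if missing:
            raise ValueError(f"period {label!r} years missing from values: {missing}")
        per_rep = values[list(years)].mean(axis=1).to_numpy()
        rows.append(
            {
                "period": label,
                "median": float(np.median(per_rep)),
                "lo90": float(np.percentile(per_rep, lo90)),
                "hi90": float(np.percentile(per_rep, hi90)),
                "lo80": float(np.percentile(per_rep, lo80)),
                "hi80": float(np.percentile(per_rep, hi80)),
            }
        )
    return pd.DataFrame(rows)


def indicator_table(
    reps: ReplicateSet,
    rp: ReferencePoints = ReferencePoints(),
    sp: StabilityParams | None = None,
    periods: PeriodDefinition | None = None,
) -> pd.DataFrame:
    """Full indicator x period summary table for one replicate set.

    Catch stability for the first projection year uses the last historical
    year's catch as the previous value, so every projection year has a
    stability value.
    """
    sp = sp or StabilityParams.from_life_history(reps.lh)
    proj_years = [int(y) for y in reps.cfg.proj_year_labels]
    periods = periods or PeriodDefinition.equal_thirds(proj_years)
    return _table_for_rule(
        reps.data,
        rule_name=reps.rule.name,
        last_hist_year=reps.cfg.last_hist_year,
        proj_years=proj_years,
        rp=rp,
        sp=sp,
        periods=periods,
    )


def indicator_table_from_frame(
    df: pd.DataFrame,
    rp: ReferencePoints = ReferencePoints(),
    cvar_max: float | None = None,
    periods: PeriodDefinition | None = None,
) -> pd.DataFrame:
    """Recompute the indicator table from a saved trajectory frame.

    ``df`` is the long-format trajectory table written by
    :meth:`ReplicateSet.to_csv` (it may hold several rules).  The carrying
    capacity is recovered from biomass / biomass_rel to derive the default
    Cvar_max = K/10 when none is given.
    """
    if "rule" not in df.columns:
        df = df.assign(rule="rule")
    proj_years = sorted(int(y) for y in df.loc[df["phase"] == "projection", "year"].unique())
    if not proj_years:
        raise ValueError("trajectory frame has no projection years")
    last_hist_year = int(df.loc[df["phase"] == "history", "year"].max())
    if cvar_max is None:
        ok = df["biomass_rel"] > 0
        K = float((df.loc[ok, "biomass"] / df.loc[ok, "biomass_rel"]).iloc[0])
        cvar_max = K / 10.0
    sp = StabilityParams(cvar_max=cvar_max)
    periods = periods or PeriodDefinition.equal_thirds(proj_years)
    pieces = [
        _table_for_rule(sub, rule_name=name, last_hist_year=last_hist_year,
                        proj_years=proj_years, rp=rp, sp=sp, periods=periods)
        for name, sub in df.groupby("rule", sort=False)
    ]
    return pd.concat(pieces, ignore_index=True)


def _table_for_rule(data, rule_name, last_hist_year, proj_years, rp, sp, periods):
    proj = data[data["phase"] == "projection"]
    pivot = lambda col: proj.pivot(index="replicate", columns="year", values=col)
    bio = pivot("biomass_rel")
    plain = {
        "biomass": bio,
        "catch": pivot("catch"),
        "relative_cpue": pivot("cpue_rel"),
        "relative_effort": pivot("effort_rel"),
    }
    # stability: prepend the last historical catch so year 1 has a delta
    all_catch = data.pivot(index="replicate", columns="year", values="catch")
    lead_in = [last_hist_year] + list(proj_years)
    stab = catch_stability(all_catch[lead_in].to_numpy(), sp)
    plain["catch_stability"] = pd.DataFrame(stab, index=bio.index, columns=proj_years)
    plain["trp_proximity"] = pd.DataFrame(
        trp_proximity(bio.to_numpy(), rp), index=bio.index, columns=proj_years
    )

    pieces = []
    for name in INDICATOR_NAMES:
        if name == "prob_above_lrp":
            p = prob_above_lrp(bio.to_numpy(), rp)
            p_by_year = dict(zip(proj_years, p))
            rows = []
            for label, years in periods.items():
                rows.append(
                    {
                        "period": label,
                        "median": float(np.mean([p_by_year[y] for y in years])),
                        "lo90": np.nan,
                        "hi90": np.nan,
                        "lo80": np.nan,
                        "hi80": np.nan,
                    }
                )
            part = pd.DataFrame(rows)
        else:
            part = summarise(plain[name], periods)
        part.insert(0, "indicator", name)
        pieces.append(part)
    table = pd.concat(pieces, ignore_index=True)
    table.insert(0, "rule", rule_name)
    return table[TABLE_COLUMNS]
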