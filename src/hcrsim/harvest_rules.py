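"""Harvest control rules and the simulated biomass-estimation step.

A harvest control rule (HCR) maps an *estimated* relative biomass (B/K,
between 0 and roughly 1) to a catch limit for the coming year.  Two rule
shapes are provided:

* :class:`ThresholdCatchRule` — the hockey stick: Cmin below Blim, Cmax
  above Belbow, linear in between.
* :class:`ConstantCatchRule` — a fixed catch limit that ignores stock
  status, included as a comparison.

No stock-assessment model is run; estimation is emulated by perturbing the
true relative biomass with multiplicative normal noise and an optional
proportional bias (:func:`estimate_biomass`).  The catch limit set by a
rule is always taken exactly (no implementation error); the operating
model's catch cap is a separate numerical guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

__all__ = [
    "ThresholdCatchRule",
    "ConstantCatchRule",
    "HarvestRule",
    "EstimationSpec",
    "estimate_biomass",
    "parse_rule_string",
    "load_rules",
    "save_rules",
]


@dataclass(frozen=True)
class ThresholdCatchRule:
    """Threshold-catch ("hockey stick") rule.

    Parameters
    ----------
    cmax, cmin : float
        Maximum and minimum allowable catch (catch units).
    blim : float
        Relative biomass at or below which the minimum catch applies.
    belbow : float
        Relative biomass at or above which the maximum catch applies.
        The long-term stock level a rule produces depends on all four
        parameters jointly, not on ``belbow`` alone.
    """

    cmax: float
    cmin: float
    blim: float
    belbow: float
    name: str = "threshold"

    def __post_init__(self) -> None:
        if not 0 <= self.cmin <= self.cmax:
            raise ValueError(f"need 0 <= cmin <= cmax, got cmin={self.cmin}, cmax={self.cmax}")
        if not 0 <= self.blim < self.belbow <= 1:
            raise ValueError(
                f"need 0 <= blim < belbow <= 1, got blim={self.blim}, belbow={self.belbow}"
            )

    def catch_limit(self, b_est):
        """Catch limit for an estimated relative biomass (scalar or array).

        Piecewise linear, continuous and non-decreasing: cmin at or below
        blim, cmax at or above belbow, linear interpolation between the
        two inflexion points.  Estimates above 1 are allowed and return
        cmax.
        """
        if np.any(np.asarray(b_est) < 0):
            raise ValueError("estimated relative biomass must be non-negative")
        out = np.interp(b_est, [self.blim, self.belbow], [self.cmin, self.cmax])
        return float(out) if np.isscalar(b_est) else out

    def to_dict(self) -> dict:
        return {
            "type": "threshold",
            "name": self.name,
            "params": {
                "cmax": self.cmax,
                "cmin": self.cmin,
                "blim": self.blim,
                "belbow": self.belbow,
            },
        }


@dataclass(frozen=True)
class ConstantCatchRule:
    """Fixed catch limit that does not respond to stock status."""

    level: float
    name: str = "constant"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("constant catch level must be non-negative")

    def catch_limit(self, b_est):
        if np.isscalar(b_est):
            return float(self.level)
        return np.full(np.shape(b_est), float(self.level))

    def to_dict(self) -> dict:
        return {"type": "constant", "name": self.name, "params": {"level": self.level}}


HarvestRule = Union[ThresholdCatchRule, ConstantCatchRule]


@dataclass(frozen=True)
class EstimationSpec:
    """Estimation error sd and proportional bias applied to true biomass.

    ``sd`` is the relative standard deviation of the estimation noise;
    ``bias`` shifts the estimate proportionally (e.g. +0.1 means biomass
    is consistently over-estimated by 10%).
    """

    sd: float = 0.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("estimation sd must be non-negative")
        if self.bias <= -1:
            raise ValueError("estimation bias must exceed -1")


def estimate_biomass(b_true, spec: EstimationSpec, rng: np.random.Generator):
    """Simulated stock-status estimate: max(0, b_true*(1 + bias + eps)).

    eps ~ Normal(0, sd).  The noise is multiplicative so the error scale is
    proportional to stock size; with sd = 0 and bias = 0 the estimate is
    exact.  Estimates above 1 are not clamped — an over-estimate can exceed
    the unfished level and the rule handles it naturally.
    """
    if np.any(np.asarray(b_true) < 0):
        raise ValueError("true relative biomass must be non-negative")
    eps = spec.sd * rng.standard_normal(np.shape(b_true) or None)
    out = np.maximum(b_true * (1.0 + spec.bias + eps), 0.0)
    return float(out) if np.isscalar(b_true) else out


def parse_rule_string(text: str) -> HarvestRule:
    """Parse a compact CLI rule spec.

    ``"threshold:140,10,0.2,0.5"`` -> ThresholdCatchRule(cmax, cmin, blim, belbow);
    ``"constant:100"`` -> ConstantCatchRule(level).  An optional display
    name may follow after ``@``, e.g. ``"threshold:140,10,0.2,0.5@HCR 1"``.
    """
    body, _, name = text.partition("@")
    kind, _, args = body.partition(":")
    kind = kind.strip().lower()
    try:
        values = [float(v) for v in args.split(",")] if args else []
    except ValueError:
        raise ValueError(f"could not parse rule parameters in {text!r}") from None
    if kind == "threshold":
        if len(values) != 4:
            raise ValueError("threshold rule needs 4 parameters: cmax,cmin,blim,belbow")
        return ThresholdCatchRule(*values, name=name or body)
    if kind == "constant":
        if len(values) != 1:
            raise ValueError("constant rule needs 1 parameter: level")
        return ConstantCatchRule(values[0], name=name or body)
    raise ValueError(f"unknown rule type {kind!r}; expected 'threshold' or 'constant'")


def rule_from_dict(d: dict) -> HarvestRule:
    kind = d.get("type")
    params = d.get("params", {})
    name = d.get("name") or kind
    if kind == "threshold":
        return ThresholdCatchRule(
            cmax=params["cmax"],
            cmin=params["cmin"],
            blim=params["blim"],
            belbow=params["belbow"],
            name=name,
        )
    if kind == "constant":
        return ConstantCatchRule(level=params["level"], name=name)
    raise ValueError(f"unknown rule type {kind!r} in basket file")


def load_rules(path: str | Path) -> list[HarvestRule]:
    """Read a basket file (YAML or JSON list of rules, or {rules: [...]})."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("rules", [])
    if not isinstance(doc, list) or not doc:
        raise ValueError(f"basket file {path} contains no rules")
    return [rule_from_dict(d) for d in doc]


def save_rules(rules: Sequence[HarvestRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"rules": [r.to_dict() for r in rules]}, fh, sort_keys=False)
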