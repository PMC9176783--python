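"""Schaefer surplus-production operating model.

The simulated "true" stock follows an annual-step Schaefer biomass dynamic

    B[y+1] = B[y] + g(B[y]) - C[y],        g(B) = r * B * (1 - B / K),

where ``r`` is the intrinsic growth rate and ``K`` the carrying capacity
(average unfished biomass).  Maximum sustainable yield is the peak of the
production curve, MSY = r*K/4, attained at B = K/2.  The model fishery is
generic: catches are unitless and ``K`` is scaled so that MSY = 100 for
every life history, which makes rules and indicators comparable across the
slow / medium / fast stocks.

This module also provides the historical catch scenarios used to condition
the stock before a projection starts, and the autocorrelated process noise
("biological variability") applied multiplicatively to surplus production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LifeHistory",
    "CatchHistoryScenario",
    "NoiseSpec",
    "make_life_history",
    "make_catch_history",
    "surplus_production",
    "realised_catch",
    "step_biomass",
    "autocorrelated_noise",
    "generate_history",
    "LIFE_HISTORY_R",
    "CATCH_HISTORY_LABELS",
    "MSY_DEFAULT",
    "CATCH_CAP_FRAC",
    "BIOMASS_FLOOR_FRAC",
]

#: Intrinsic growth rate for each named life history (1/year).
LIFE_HISTORY_R = {"slow": 0.2, "medium": 0.6, "fast": 1.0}

CATCH_HISTORY_LABELS = ("under", "fully", "over")

#: MSY every default life history is scaled to (catch units).
MSY_DEFAULT = 100.0

#: Realised catch may not exceed this fraction of the start-of-year biomass.
#: A numerical guard, not a biological claim; binding events are reported.
CATCH_CAP_FRAC = 0.95

#: Biomass is floored at this fraction of K so the dynamics stay defined.
BIOMASS_FLOOR_FRAC = 1e-6


@dataclass(frozen=True)
class LifeHistory:
    """Stock life history: growth rate ``r`` with ``K`` pinned to the MSY.

    ``K`` is derived as ``4 * msy / r`` so that ``r * K / 4 == msy``
    exactly.  Arbitrary positive ``r`` is accepted for custom stocks; the
    three named defaults are built by :func:`make_life_history`.
    """

    label: str
    r: float
    msy: float = MSY_DEFAULT

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"intrinsic growth rate must be positive, got {self.r}")
        if not self.msy > 0:
            raise ValueError(f"msy must be positive, got {self.msy}")

    @property
    def K(self) -> float:
        """Carrying capacity (catch units of biomass), 4*MSY/r."""
        return 4.0 * self.msy / self.r

    @property
    def biomass_floor(self) -> float:
        return BIOMASS_FLOOR_FRAC * self.K


def make_life_history(label: str, msy: float = MSY_DEFAULT) -> LifeHistory:
    """Build one of the named life histories (slow, medium or fast)."""
    try:
        r = LIFE_HISTORY_R[label]
    except KeyError:
        raise ValueError(
            f"unknown life history {label!r}; expected one of {sorted(LIFE_HISTORY_R)}"
        ) from None
    return LifeHistory(label=label, r=r, msy=msy)


@dataclass(frozen=True)
class CatchHistoryScenario:
    """Historical exploitation pattern used to condition the stock.

    * ``under``  — catch constant at 2/3 of MSY
    * ``fully``  — catch constant at MSY
    * ``over``   — catch ramping linearly from 3/4 to 4/3 of MSY

    Multiplicative normal noise with relative sd ``noise_sd`` is applied to
    the nominal catches when a history is generated.
    """

    label: str
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.label not in CATCH_HISTORY_LABELS:
            raise ValueError(
                f"unknown catch history {self.label!r}; "
                f"expected one of {CATCH_HISTORY_LABELS}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def nominal_series(self, msy: float, n_hist: int) -> np.ndarray:
        """Per-year nominal catch before noise, length ``n_hist``."""
        if n_hist < 2:
            raise ValueError("a catch history needs at least 2 years")
        if self.label == "under":
            return np.full(n_hist, (2.0 / 3.0) * msy)
        if self.label == "fully":
            return np.full(n_hist, float(msy))
        return np.linspace(0.75 * msy, (4.0 / 3.0) * msy, n_hist)


def make_catch_history(label: str, noise_sd: float = 0.1) -> CatchHistoryScenario:
    return CatchHistoryScenario(label=label, noise_sd=noise_sd)


@dataclass(frozen=True)
class NoiseSpec:
    """Biological variability: marginal sd and lag-1 autocorrelation."""

    sd: float = 0.2
    rho: float = 0.5

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


def surplus_production(B, lh: LifeHistory):
    """Annual surplus production g(B) = r*B*(1 - B/K).

    Accepts a scalar or array biomass; negative biomass is rejected.
    The maximum over B is r*K/4 (= MSY), at B = K/2.
    """
    if np.any(np.asarray(B) < 0):
        raise ValueError("biomass must be non-negative")
    return lh.r * B * (1.0 - B / lh.K)


def realised_catch(B: float, catch_limit: float, cap_frac: float = CATCH_CAP_FRAC) -> float:
    """Catch actually taken: the limit, capped at ``cap_frac`` of biomass."""
    return min(catch_limit, cap_frac * B)


def step_biomass(
    B: float,
    C: float,
    lh: LifeHistory,
    eps: float = 0.0,
    cap_frac: float = CATCH_CAP_FRAC,
) -> float:
    """Advance biomass one year: B + g(B)*(1 + eps) - realised catch.

    ``eps`` is the biological-variability multiplier for the year (0 gives
    the deterministic dynamic).  The result is floored at a tiny fraction
    of K so the stock cannot go negative.
    """
    if B < 0:
        raise ValueError("biomass must be non-negative")
    if C < 0:
        raise ValueError("catch must be non-negative")
    c = realised_catch(B, C, cap_frac)
    b_next = B + surplus_production(B, lh) * (1.0 + eps) - c
    return max(b_next, lh.biomass_floor)


def autocorrelated_noise(n: int, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise sequence of length ``n``.

    x[y] = rho * x[y-1] + sqrt(1 - rho^2) * sd * z[y], with the initial
    state drawn from the stationary distribution, so the marginal sd is
    ``spec.sd`` and the lag-1 autocorrelation ``spec.rho`` for every year.
    Always consumes ``n + 1`` standard normals from ``rng`` so that draw
    alignment is preserved when the sd is changed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    z = rng.standard_normal(n + 1)
    if spec.sd == 0.0:
        return np.zeros(n)
    innov_scale = math.sqrt(1.0 - spec.rho**2) * spec.sd
    x = np.empty(n)
    prev = spec.sd * z[0]  # stationary initial state
    for i in range(n):
        prev = spec.rho * prev + innov_scale * z[i + 1]
        x[i] = prev
    return x


def generate_history(
    scenario: CatchHistoryScenario,
    lh: LifeHistory,
    n_hist: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the historical period, starting from the unfished stock.

    Biomass starts at K in the first historical year.  Each year's catch is
    nominal * (1 + nu), nu ~ Normal(0, noise_sd), floored at zero and capped
    at the available-biomass fraction; biomass is propagated deterministically
    (no biological variability during history).

    Returns
    -------
    biomass : ndarray, shape (n_hist + 1,)
        Start-of-year biomass; the final element is the biomass at the
        start of the first projection year.
    catch : ndarray, shape (n_hist,)
        Realised catch in each historical year.
    """
    if n_hist < 2:
        raise ValueError("n_hist must be >= 2")
    nominal = scenario.nominal_series(lh.msy, n_hist)
    nu = scenario.noise_sd * rng.standard_normal(n_hist)
    intended = np.maximum(nominal * (1.0 + nu), 0.0)
    biomass = np.empty(n_hist + 1)
    catch = np.empty(n_hist)
    biomass[0] = lh.K
    for y in range(n_hist):
        catch[y] = realised_catch(biomass[y], intended[y])
        biomass[y + 1] = step_biomass(biomass[y], catch[y], lh, eps=0.0)
    return biomass, catch
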