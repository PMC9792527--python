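"""Static N & P mass-balance ledger for a shrimp grow-out site.

The budget partitions feed-borne nitrogen and phosphorus at a set of
checkpoint days into: nutrient in the delivered feed, nutrient in unconsumed
(wasted) feed, nutrient retained in shrimp body mass, and nutrient excreted,
and sums the unconsumed and excreted parts into the inorganic load entering
the receiving water. Per-hectare rows are scaled by farm area to site totals.

Two excretion conventions are shipped:

``table1``
    excreted = feed nutrient - retained nutrient. This is the bookkeeping
    used in the published farm ledgers this module reproduces; it labels all
    non-retained nutrient as excretion, so the inorganic load
    (unconsumed + excreted) counts unconsumed feed twice relative to a
    strict balance.
``strict``
    excreted = feed nutrient - unconsumed nutrient - retained nutrient,
    which conserves mass exactly: feed = unconsumed + retained + excreted.

Monitored rows (biomass, feed, unconsumed feed) may be supplied directly on
each checkpoint; when absent they are derived from survivors x weight and
feed x loss fraction respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .units import grams_to_tons

Convention = Literal["table1", "strict"]

#: Default nutrient mass fractions: N and P as fractions of feed mass and of
#: shrimp wet body mass.
DEFAULT_N_FEED = 0.065
DEFAULT_P_FEED = 0.014
DEFAULT_N_SHRIMP = 0.03
DEFAULT_P_SHRIMP = 0.01


@dataclass(frozen=True)
class NutrientFractions:
    """Mass fractions of N and P in feed and in shrimp wet mass (unitless)."""

    n_feed: float = DEFAULT_N_FEED
    p_feed: float = DEFAULT_P_FEED
    n_shrimp: float = DEFAULT_N_SHRIMP
    p_shrimp: float = DEFAULT_P_SHRIMP

    def __post_init__(self) -> None:
        for name in ("n_feed", "p_feed", "n_shrimp", "p_shrimp"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")


@dataclass(frozen=True)
class Checkpoint:
    """State of one hectare of ponds on a given breeding day.

    ``biomass_t_per_ha`` and ``unconsumed_feed_t_per_ha`` are optional
    monitored values; left as None they are derived from the other fields.
    """

    day: int
    survivors_per_ha: float
    weight_g: float
    cum_feed_t_per_ha: float
    biomass_t_per_ha: float | None = None
    unconsumed_feed_t_per_ha: float | None = None

    def __post_init__(self) -> None:
        if self.survivors_per_ha < 0:
            raise ValueError("survivors_per_ha must be >= 0")
        if self.weight_g < 0:
            raise ValueError("weight_g must be >= 0")
        if self.cum_feed_t_per_ha < 0:
            raise ValueError("cum_feed_t_per_ha must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """A rearing scenario: farm area, checkpoint schedule and coefficients.

    ``loss_frac`` is the fraction of delivered feed left unconsumed;
    ``fcr`` (feed conversion ratio) is carried as metadata only and does not
    enter the budget arithmetic.
    """

    area_ha: float
    checkpoints: Sequence[Checkpoint]
    loss_frac: float
    fcr: float | None = None
    fractions: NutrientFractions = field(default_factory=NutrientFractions)
    name: str = ""

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("area_ha must be > 0")
        if not 0.0 <= self.loss_frac < 1.0:
            raise ValueError("loss_frac must lie in [0, 1)")
        days = [c.day for c in self.checkpoints]
        if days != sorted(days) or len(set(days)) != len(days):
            raise ValueError("checkpoint days must be strictly increasing")
        feeds = [c.cum_feed_t_per_ha for c in self.checkpoints]
        if any(b > a for a, b in zip(feeds[1:], feeds)):
            raise ValueError("cumulative feed must be non-decreasing")


@dataclass(frozen=True)
class BudgetRow:
    """Per-hectare nutrient ledger at one checkpoint day (all masses t/ha)."""

    day: int
    biomass_t_per_ha: float
    feed_t_per_ha: float
    n_feed_t: float
    p_feed_t: float
    unconsumed_feed_t: float
    unconsumed_n_t: float
    unconsumed_p_t: float
    meat_n_t: float
    meat_p_t: float
    excreted_n_t: float
    excreted_p_t: float
    inorganic_n_load_t: float
    inorganic_p_load_t: float


@dataclass(frozen=True)
class BudgetTable:
    """Budget ledger for a scenario: per-hectare rows plus site totals."""

    scenario: ScenarioSpec
    rows: tuple[BudgetRow, ...]
    convention: Convention

    @property
    def site_n_total_t(self) -> float:
        """Site-wide inorganic N load (t): final per-ha load x area."""
        return site_total(self.rows[-1].inorganic_n_load_t, self.scenario.area_ha)

    @property
    def site_p_total_t(self) -> float:
        """Site-wide inorganic P load (t): final per-ha load x area."""
        return site_total(self.rows[-1].inorganic_p_load_t, self.scenario.area_ha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def biomass_per_ha(survivors: float, weight_g: float) -> float:
    """Standing biomass in t/ha from survivor density and individual weight.

    Parameters
    ----------
    survivors : individuals per hectare
    weight_g : mean individual wet weight in grams
    """
    if survivors < 0 or weight_g < 0:
        raise ValueError("survivors and weight must be >= 0")
    return grams_to_tons(survivors * weight_g)


def feed_nutrient(feed_mass_t: float, fraction: float) -> float:
    """Nutrient mass (t) contained in a feed mass given its mass fraction."""
    if feed_mass_t < 0:
        raise ValueError("feed_mass_t must be >= 0")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return feed_mass_t * fraction


def unconsumed_feed(feed_mass_t: float, loss_frac: float) -> float:
    """Mass of delivered feed (t) left unconsumed at loss fraction ``loss_frac``."""
    if feed_mass_t < 0:
        raise ValueError("feed_mass_t must be >= 0")
    if not 0.0 <= loss_frac < 1.0:
        raise ValueError("loss_frac must lie in [0, 1)")
    return feed_mass_t * loss_frac


def retained_nutrient(biomass_t: float, body_fraction: float) -> float:
    """Nutrient mass (t) retained in shrimp bodies of total mass ``biomass_t``."""
    if biomass_t < 0:
        raise ValueError("biomass_t must be >= 0")
    if not 0.0 <= body_fraction <= 1.0:
        raise ValueError("body_fraction must lie in [0, 1]")
    return biomass_t * body_fraction


def excreted_nutrient(
    feed_nutrient_t: float,
    retained_t: float,
    unconsumed_nutrient_t: float = 0.0,
    convention: Convention = "table1",
) -> float:
    """Excreted nutrient mass (t) under the chosen bookkeeping convention.

    ``table1``: feed - retained (unconsumed ignored).
    ``strict``: feed - unconsumed - retained (mass-conserving).
    Negative balances are clamped to zero with a warning.
    """
    if min(feed_nutrient_t, retained_t, unconsumed_nutrient_t) < 0:
        raise ValueError("all inputs must be >= 0")
    if convention == "table1":
        out = feed_nutrient_t - retained_t
    elif convention == "strict":
        out = feed_nutrient_t - unconsumed_nutrient_t - retained_t
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if out < 0:
        warnings.warn(
            "retained (+ unconsumed) nutrient exceeds feed nutrient; "
            "excretion clamped to 0",
            stacklevel=2,
        )
        out = 0.0
    return out


def inorganic_load(unconsumed_nutrient_t: float, excreted_t: float) -> float:
    """Inorganic nutrient load to the receiving water: unconsumed + excreted."""
    if unconsumed_nutrient_t < 0 or excreted_t < 0:
        raise ValueError("inputs must be >= 0")
    return unconsumed_nutrient_t + excreted_t


def site_total(per_ha_load_t: float, area_ha: float) -> float:
    """Scale a per-hectare load (t/ha) to the whole site (t)."""
    if area_ha <= 0:
        raise ValueError("area_ha must be > 0")
    return per_ha_load_t * area_ha


def removal_efficiency(input_load_t: float, output_load_t: float) -> float:
    """Fraction of the input load removed between site outlet and receiving water.

    Returns 1 - output/input; negative when output exceeds input (reported,
    never clamped).
    """
    if input_load_t <= 0:
        raise ValueError("input_load_t must be > 0")
    if output_load_t < 0:
        raise ValueError("output_load_t must be >= 0")
    return 1.0 - output_load_t / input_load_t


def _build_row(cp: Checkpoint, scenario: ScenarioSpec, convention: Convention) -> BudgetRow:
    fr = scenario.fractions
    biomass = (
        cp.biomass_t_per_ha
        if cp.biomass_t_per_ha is not None
        else biomass_per_ha(cp.survivors_per_ha, cp.weight_g)
    )
    feed = cp.cum_feed_t_per_ha
    n_feed = feed_nutrient(feed, fr.n_feed)
    p_feed = feed_nutrient(feed, fr.p_feed)
    uncons = (
        cp.unconsumed_feed_t_per_ha
        if cp.unconsumed_feed_t_per_ha is not None
        else unconsumed_feed(feed, scenario.loss_frac)
    )
    uncons_n = feed_nutrient(uncons, fr.n_feed)
    uncons_p = feed_nutrient(uncons, fr.p_feed)
    meat_n = retained_nutrient(biomass, fr.n_shrimp)
    meat_p = retained_nutrient(biomass, fr.p_shrimp)
    excr_n = excreted_nutrient(n_feed, meat_n, uncons_n, convention)
    excr_p = excreted_nutrient(p_feed, meat_p, uncons_p, convention)
    return BudgetRow(
        day=cp.day,
        biomass_t_per_ha=biomass,
        feed_t_per_ha=feed,
        n_feed_t=n_feed,
        p_feed_t=p_feed,
        unconsumed_feed_t=uncons,
        unconsumed_n_t=uncons_n,
        unconsumed_p_t=uncons_p,
        meat_n_t=meat_n,
        meat_p_t=meat_p,
        excreted_n_t=excr_n,
        excreted_p_t=excr_p,
        inorganic_n_load_t=inorganic_load(uncons_n, excr_n),
        inorganic_p_load_t=inorganic_load(uncons_p, excr_p),
    )


def build_budget_table(scenario: ScenarioSpec, convention: Convention = "table1") -> BudgetTable:
    """Build the full per-hectare budget ledger for a scenario.

    One :class:`BudgetRow` per checkpoint; site totals are exposed on the
    returned :class:`BudgetTable`.
    """
    if not scenario.checkpoints:
        raise ValueError("scenario has no checkpoints")
    rows = tuple(_build_row(cp, scenario, convention) for cp in scenario.checkpoints)
    return BudgetTable(scenario=scenario, rows=rows, convention=convention)
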