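"""Stock-and-flow simulator of pond nitrogen over a grow-out season.

The model is a system-dynamics (STELLA-style) formulation with six stocks —
individual nitrogen weight, total nitrogen discharged, individual count,
cumulative excreted N, cumulative unconsumed-feed N losses and cumulative
faecal N — advanced by explicit Euler steps. All flows are evaluated at the
old state and the stocks updated simultaneously, the conventional Euler
semantics of system-dynamics software.

The equations are implemented literally, including their discontinuous
rules: total mortality once individual body weight reaches 20 g, harvest
beginning at 10 g, and a nitrogen-accumulation term that switches, once
harvest begins, from the excretion flow alone to excretion plus the
accumulated faecal and feed-loss stocks. Because of that switch the total
discharged nitrogen grows without bound after harvest onset, so the
seasonal maximum outlet concentration reported for a grow-out is taken over
the grow-out (pre-harvest) phase; see :func:`peak_concentration`.

The model carries its own internal unit scales (e.g. the 0.2 factor in the
biomass expression); the outlet concentration Ntotal / natural_current / 1000
is reported in mg/l at the reporting layer only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "StellaParams",
    "StellaState",
    "StellaAux",
    "compute_aux",
    "init_state",
    "euler_step",
    "simulate",
    "peak_concentration",
]


@dataclass(frozen=True)
class StellaParams:
    """Constants of the pond-nitrogen model.

    Defaults are the 830-pond / 240,000-individuals-per-pond configuration;
    the reduced-stocking configuration substitutes ``pond_number=1251``,
    ``init_number=100000``.
    """

    pond_number: float = 830.0
    init_number: float = 240000.0
    #: outlet-channel flow constant (L/s) dividing Ntotal into a concentration
    natural_current: float = 140.0
    #: initial individual nitrogen weight (model units)
    init_ind_weight_n: float = 0.027
    #: divisor converting nitrogen weight to body weight (g)
    weight_conv: float = 0.0285
    #: daily ration as a fraction of body weight
    feed_rate: float = 0.03
    #: multiplier in the total-food expression
    food_scale: float = 1.287
    #: chained assimilation factors applied to the individual ration
    assim_factors: tuple[float, ...] = (0.16, 0.3, 0.9, 0.5)
    #: chained factors applied to total food in the excretion pathway
    excretion_factors: tuple[float, ...] = (0.3, 0.16, 0.85)
    #: fraction of the excretion pathway diverted to faeces
    faeces_factor_extra: float = 0.1
    #: extra loss fraction subtracted inside the excretion expression
    excretion_loss_extra: float = 0.25
    #: fraction of total food left unconsumed (after the 0.3 x 0.16 chain)
    unconsumed_factor_extra: float = 0.15
    #: factor in the biomass expression
    biomass_factor: float = 0.2
    #: daily mortality fraction below the wipeout threshold
    mortality_rate: float = 0.01
    #: body weight (g) at which mortality switches to total wipeout
    mortality_weight_threshold: float = 20.0
    #: body weight (g) at which harvest begins
    harvest_weight_threshold: float = 10.0
    #: initial excreted-N stock as a fraction of initial total food
    init_excreted_factor: float = 0.077
    #: initial faecal stock as a fraction of the initial individual ration
    init_fecal_factor: float = 0.26
    dt: float = 1.0
    horizon: float = 120.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.horizon < self.dt:
            raise ValueError("horizon must be >= dt")
        if self.harvest_weight_threshold > self.mortality_weight_threshold:
            raise ValueError("harvest threshold must not exceed mortality threshold")
        for name in ("pond_number", "init_number", "natural_current", "weight_conv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StellaState:
    """The six stocks at time ``t`` (model units)."""

    t: float
    ind_weight_n: float
    ntotal: float
    number: float
    n_excreted: float
    n_losses: float
    total_fecal: float


@dataclass(frozen=True)
class StellaAux:
    """Auxiliary (flow and converter) values evaluated at one state."""

    ind_weight_b: float
    ind_food: float
    total_food: float
    biomass: float
    harvest: float
    mortality: float
    assimilation: float
    excretion: float
    unconsumed: float
    faeces_product: float
    n_accumulation: float
    n_concentration: float


def _prod(factors: tuple[float, ...]) -> float:
    out = 1.0
    for f in factors:
        out *= f
    return out


def compute_aux(state: StellaState, params: StellaParams) -> StellaAux:
    """Evaluate every auxiliary expression at ``state`` (pure function)."""
    for name in ("ind_weight_n", "ntotal", "number", "n_excreted", "n_losses", "total_fecal"):
        if not math.isfinite(getattr(state, name)):
            raise ValueError(f"non-finite stock {name} at t={state.t}")
    ind_weight_b = state.ind_weight_n / params.weight_conv
    ind_food = ind_weight_b * params.feed_rate
    biomass = state.number * ind_weight_b * params.biomass_factor
    total_food = biomass * ind_food * params.food_scale
    if ind_weight_b < params.mortality_weight_threshold:
        mortality = params.mortality_rate * state.number
    else:
        mortality = state.number
    if ind_weight_b < params.harvest_weight_threshold:
        harvest = 0.0
    else:
        harvest = mortality * ind_weight_b
    excr_chain = total_food * _prod(params.excretion_factors)
    faeces_product = excr_chain * params.faeces_factor_extra
    excretion = excr_chain - (faeces_product + excr_chain * params.excretion_loss_extra)
    unconsumed = (
        total_food
        * params.excretion_factors[0]
        * params.excretion_factors[1]
        * params.unconsumed_factor_extra
    )
    assimilation = ind_food * _prod(params.assim_factors)
    if harvest == 0.0:
        n_accumulation = params.pond_number * excretion
    else:
        n_accumulation = params.pond_number * (excretion + state.total_fecal + state.n_losses)
    n_concentration = state.ntotal / params.natural_current / 1000.0
    return StellaAux(
        ind_weight_b=ind_weight_b,
        ind_food=ind_food,
        total_food=total_food,
        biomass=biomass,
        harvest=harvest,
        mortality=mortality,
        assimilation=assimilation,
        excretion=excretion,
        unconsumed=unconsumed,
        faeces_product=faeces_product,
        n_accumulation=n_accumulation,
        n_concentration=n_concentration,
    )


def init_state(params: StellaParams) -> StellaState:
    """Initial stocks.

    Two of the initial stocks are defined in terms of auxiliaries (total
    food and individual ration), so initialization is two-pass: auxiliaries
    are evaluated from the initial nitrogen weight and count first, then the
    dependent stocks are set.
    """
    provisional = StellaState(
        t=0.0,
        ind_weight_n=params.init_ind_weight_n,
        ntotal=0.0,
        number=params.init_number,
        n_excreted=0.0,
        n_losses=0.0,
        total_fecal=0.0,
    )
    aux = compute_aux(provisional, params)
    return replace(
        provisional,
        n_excreted=params.init_excreted_factor * aux.total_food,
        total_fecal=params.init_fecal_factor * aux.ind_food,
    )


def euler_step(state: StellaState, params: StellaParams, dt: float | None = None) -> StellaState:
    """Advance all stocks by one explicit Euler step of length ``dt``.

    Flows come from :func:`compute_aux` at the old state; the individual
    count is clamped at zero after the mortality outflow.
    """
    if dt is None:
        dt = params.dt
    if dt < 0:
        raise ValueError("dt must be >= 0")
    aux = compute_aux(state, params)
    return StellaState(
        t=state.t + dt,
        ind_weight_n=state.ind_weight_n + aux.assimilation * dt,
        ntotal=state.ntotal + aux.n_accumulation * dt,
        number=max(0.0, state.number - aux.mortality * dt),
        n_excreted=state.n_excreted + aux.excretion * dt,
        n_losses=state.n_losses + aux.unconsumed * dt,
        total_fecal=state.total_fecal + aux.faeces_product * dt,
    )


_STOCK_COLS = ("t", "ind_weight_n", "ntotal", "number", "n_excreted", "n_losses", "total_fecal")
_AUX_COLS = (
    "ind_weight_b",
    "ind_food",
    "total_food",
    "biomass",
    "harvest",
    "mortality",
    "assimilation",
    "excretion",
    "unconsumed",
    "faeces_product",
    "n_accumulation",
    "n_concentration",
)


def simulate(params: StellaParams) -> pd.DataFrame:
    """Run the model over ``params.horizon`` days with step ``params.dt``.

    Returns a tidy DataFrame with one row per recorded time (including t=0)
    and a column per stock and auxiliary; ``n_concentration`` is the outlet
    concentration interpreted in mg/l. Deterministic given ``params``.
    """
    n_steps = round(params.horizon / params.dt)
    if n_steps < 1:
        raise ValueError("horizon/dt must yield at least one step")
    state = init_state(params)
    records = []
    for step in range(n_steps + 1):
        aux = compute_aux(state, params)
        row = {c: getattr(state, c) for c in _STOCK_COLS}
        row.update({c: getattr(aux, c) for c in _AUX_COLS})
        records.append(row)
        if step == n_steps:
            break
        state = euler_step(state, params)
        if not math.isfinite(state.ntotal):
            raise OverflowError(f"numeric overflow at step {step + 1}")
    return pd.DataFrame.from_records(records)


def peak_concentration(
    trajectory: pd.DataFrame, phase: str = "grow_out"
) -> tuple[float, float]:
    """Day and value of the maximum outlet N concentration (mg/l).

    ``phase="grow_out"`` (default) restricts the search to the grow-out
    phase: all rows up to and including the first row at which harvest is
    active. At that row the discharged-N stock still reflects only grow-out
    flows (flows are evaluated at old states), so this is the seasonal
    maximum attributable to the rearing period itself. After the harvest
    switch the literal equations recycle accumulated stocks into the
    accumulation flow and the concentration grows without bound, which is
    why ``phase="full"`` (the raw trajectory maximum) is not the default.
    """
    if trajectory.empty:
        raise ValueError("empty trajectory")
    if phase == "grow_out":
        harvested = trajectory.index[trajectory["harvest"] > 0]
        sub = trajectory if len(harvested) == 0 else trajectory.loc[: harvested[0]]
    elif phase == "full":
        sub = trajectory
    else:
        raise ValueError(f"unknown phase {phase!r}")
    idx = sub["n_concentration"].idxmax()
    return float(sub.loc[idx, "t"]), float(sub.loc[idx, "n_concentration"])
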