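"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its spec (seed included) and returns
the generated data together with its ground truth, so every downstream
estimator has a recovery test that needs no external data:

* :func:`generate_outlet_series` — a daily grow-out-season monitoring
  series (one 11:00 reading per day) of outlet discharge and total-N
  concentration. The latent concentration follows a monotone exponential
  ramp tracking the growing biomass, with a sudden step increase late in
  the season (default day 90); discharge fluctuates around a base value by
  a ±10% seasonal sinusoid plus jitter, reflecting routine water exchange.
  Observed concentrations carry multiplicative lognormal noise with unit
  mean (so the latent series is the expectation of the observed one); the
  true period load is computed from the noise-free latent series.
* :func:`generate_scenario` — a rearing scenario with exponential growth
  and survival curves, feed tied to biomass through the feed conversion
  ratio.
* :func:`generate_foodweb` — taxon-level isotope samples positioned at
  known trophic-level offsets above a baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .budget import Checkpoint, NutrientFractions, ScenarioSpec
from .isotopes import FractionationConstants, IsotopeSample
from .load import OutletRecord
from .units import flow_concentration_to_tons_per_day

__all__ = [
    "OutletSeriesSpec",
    "FoodWebSpec",
    "generate_outlet_series",
    "generate_scenario",
    "generate_foodweb",
]

#: per-day exponential growth rate implied by the dynamic model's
#: assimilation chain: (ration fraction / N-to-body conversion) x assimilated
#: fraction of the ration
DEFAULT_GROWTH_RATE = 0.03 / 0.0285 * (0.16 * 0.3 * 0.9 * 0.5)


@dataclass(frozen=True)
class OutletSeriesSpec:
    """Parameters of a synthetic daily outlet monitoring series.

    One record per breeding day (the single fixed-hour reading of the
    monitoring station). Defaults emulate a 120-day season with a 140 L/s
    outlet flow and a latent concentration ramping to ~190 mg/l by season
    end including the day-90 step increase.
    """

    season_days: int = 120
    base_discharge_lps: float = 140.0
    base_concentration_mgl: float = 15.0
    #: per-day exponential rate of the latent concentration ramp
    ramp_rate: float = 0.0175
    spike_day: int = 90
    spike_multiplier: float = 1.5
    #: relative amplitude of the seasonal discharge sinusoid
    discharge_amplitude: float = 0.10
    #: relative sd of day-to-day discharge jitter
    discharge_jitter_sd: float = 0.02
    #: sigma of the multiplicative lognormal concentration noise
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season_days < 1:
            raise ValueError("season_days must be >= 1")
        if not 1 <= self.spike_day <= self.season_days:
            raise ValueError("spike_day must fall within the season")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def latent_concentration(spec: OutletSeriesSpec, day: np.ndarray) -> np.ndarray:
    """Noise-free latent concentration (mg/l) on the given breeding days."""
    day = np.asarray(day, dtype=float)
    ramp = np.exp(spec.ramp_rate * day)
    spike = np.where(day >= spec.spike_day, spec.spike_multiplier, 1.0)
    return spec.base_concentration_mgl * ramp * spike


def generate_outlet_series(spec: OutletSeriesSpec) -> tuple[list[OutletRecord], float]:
    """Generate a daily outlet series and return it with its true total load.

    The true load is the exact sum of daily discharge x latent concentration
    over the season (tons); observed concentrations multiply the latent
    series by unit-mean lognormal noise exp(N(-sigma^2/2, sigma^2)).
    """
    rng = np.random.default_rng(spec.seed)
    day = np.arange(1, spec.season_days + 1)
    q = spec.base_discharge_lps * (
        1.0
        + spec.discharge_amplitude * np.sin(2 * np.pi * day / spec.season_days)
        + rng.normal(0.0, spec.discharge_jitter_sd, size=spec.season_days)
    )
    q = np.clip(q, 0.0, None)
    latent = latent_concentration(spec, day)
    if spec.noise_sigma > 0:
        noise = rng.lognormal(
            mean=-0.5 * spec.noise_sigma**2, sigma=spec.noise_sigma, size=spec.season_days
        )
    else:
        noise = np.ones(spec.season_days)
    conc = latent * noise
    true_total = float(flow_concentration_to_tons_per_day(q, latent).sum())
    series = [
        OutletRecord(day=int(d), discharge_lps=float(qi), concentration_mgl=float(ci))
        for d, qi, ci in zip(day, q, conc)
    ]
    return series, true_total


def generate_scenario(
    area_ha: float,
    density_per_ha: float,
    fcr: float = 1.29,
    loss_frac: float = 0.30,
    growth_rate: float = DEFAULT_GROWTH_RATE,
    init_weight_g: float | None = None,
    checkpoint_days: tuple[int, ...] = (50, 80, 110),
    mortality_per_day: float = 0.002,
    fractions: NutrientFractions | None = None,
    name: str = "synthetic",
) -> ScenarioSpec:
    """Build a rearing scenario from growth and survival curves.

    Individual weight grows exponentially at ``growth_rate``; by default the
    initial weight is set so the final checkpoint reaches ~15.5 g, the
    market weight of a grow-out. Survivors decline exponentially at
    ``mortality_per_day``; cumulative feed is biomass x ``fcr``. The
    scenario is deterministic, hence its own ground truth.
    """
    if area_ha <= 0:
        raise ValueError("area_ha must be > 0")
    if density_per_ha < 0:
        raise ValueError("density_per_ha must be >= 0")
    if init_weight_g is None:
        init_weight_g = 15.5 * math.exp(-growth_rate * checkpoint_days[-1])
    checkpoints = []
    for day in checkpoint_days:
        weight = init_weight_g * math.exp(growth_rate * day)
        survivors = density_per_ha * math.exp(-mortality_per_day * day)
        biomass = survivors * weight * 1e-6
        checkpoints.append(
            Checkpoint(
                day=day,
                survivors_per_ha=survivors,
                weight_g=weight,
                cum_feed_t_per_ha=biomass * fcr,
            )
        )
    return ScenarioSpec(
        area_ha=area_ha,
        checkpoints=tuple(checkpoints),
        loss_frac=loss_frac,
        fcr=fcr,
        fractions=fractions if fractions is not None else NutrientFractions(),
        name=name,
    )


@dataclass(frozen=True)
class FoodWebSpec:
    """Parameters of a synthetic isotope food web.

    ``taxa`` maps taxon names to trophic-level offsets above the baseline
    (1.0 = one full level); each taxon's δ values are the baseline plus
    offset x per-level fractionation, observed with per-individual Gaussian
    noise of sd ``sd_permil`` across ``n_per_taxon`` individuals.
    """

    baseline_taxon: str = "gammaridae"
    baseline_d13c: float = -16.9
    baseline_d15n: float = 4.6
    baseline_level: float = 2.0
    taxa: dict[str, float] = field(
        default_factory=lambda: {"shrimp": 1.0, "goby": 1.66, "mullet": 0.54}
    )
    constants: FractionationConstants = field(default_factory=FractionationConstants)
    sd_permil: float = 0.5
    n_per_taxon: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_taxon < 1:
            raise ValueError("n_per_taxon must be >= 1")
        if self.sd_permil < 0:
            raise ValueError("sd_permil must be >= 0")


def generate_foodweb(spec: FoodWebSpec) -> tuple[list[IsotopeSample], dict[str, float]]:
    """Generate taxon-level isotope samples and their true trophic levels.

    Returns one :class:`IsotopeSample` per taxon (baseline first) carrying
    the sample mean, sd and n over the simulated individuals, plus a map of
    taxon -> true trophic level.
    """
    rng = np.random.default_rng(spec.seed)
    truth = {spec.baseline_taxon: spec.baseline_level}
    samples = []

    def _sample(taxon: str, true_c: float, true_n: float) -> IsotopeSample:
        c_obs = true_c + rng.normal(0.0, spec.sd_permil, size=spec.n_per_taxon)
        n_obs = true_n + rng.normal(0.0, spec.sd_permil, size=spec.n_per_taxon)
        many = spec.n_per_taxon > 1
        return IsotopeSample(
            taxon=taxon,
            d13c=float(c_obs.mean()),
            d15n=float(n_obs.mean()),
            d13c_sd=float(c_obs.std(ddof=1)) if many else None,
            d15n_sd=float(n_obs.std(ddof=1)) if many else None,
            n=spec.n_per_taxon,
            reference_taxon=None if taxon == spec.baseline_taxon else spec.baseline_taxon,
        )

    samples.append(_sample(spec.baseline_taxon, spec.baseline_d13c, spec.baseline_d15n))
    for taxon, offset in spec.taxa.items():
        truth[taxon] = spec.baseline_level + offset
        samples.append(
            _sample(
                taxon,
                spec.baseline_d13c + offset * spec.constants.delta_c_per_level,
                spec.baseline_d15n + offset * spec.constants.delta_n_per_level,
            )
        )
    return samples, truth
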