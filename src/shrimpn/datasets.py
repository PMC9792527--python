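"""Packaged datasets: the published grow-out scenarios and food-web isotope
table, plus the printed ledger cells used by the regression tests.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd
import yaml

from .budget import Checkpoint, NutrientFractions, ScenarioSpec
from .isotopes import IsotopeSample

__all__ = [
    "gomishan_scenarios",
    "gomishan_budget_printed",
    "foodweb_samples",
    "foodweb_pairs",
    "headline_loads",
]

_FIXTURES = files("shrimpn.fixtures")

#: Headline site loads (tons per breeding season) reported for the 2018
#: configuration: the mass-balance N load entering the lagoon and the
#: rating-curve N load measured leaving the outlet channel.
HEADLINE_INPUT_N_T = 220.157
HEADLINE_OUTPUT_N_T = 121.8


def scenario_from_dict(data: dict) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a plain mapping (YAML/JSON layout)."""
    checkpoints = tuple(Checkpoint(**cp) for cp in data["checkpoints"])
    fractions = NutrientFractions(**data["fractions"]) if "fractions" in data else NutrientFractions()
    return ScenarioSpec(
        area_ha=data["area_ha"],
        checkpoints=checkpoints,
        loss_frac=data["loss_frac"],
        fcr=data.get("fcr"),
        fractions=fractions,
        name=str(data.get("name", "")),
    )


def gomishan_scenarios() -> dict[str, ScenarioSpec]:
    """The two published rearing scenarios (2018: 830 ha, 2021: 1251 ha)."""
    raw = yaml.safe_load(_FIXTURES.joinpath("table1_scenarios.yaml").read_text())
    return {key: scenario_from_dict(val) for key, val in raw.items()}


def gomishan_budget_printed() -> pd.DataFrame:
    """Printed per-hectare ledger cells (scenario, day, quantity, printed).

    ``printed`` is kept as a string so each cell's printed decimal places
    can be recovered for rounding-aware comparison.
    """
    with _FIXTURES.joinpath("table1_printed.csv").open() as fh:
        return pd.read_csv(fh, dtype={"printed": str})


def foodweb_samples() -> list[IsotopeSample]:
    """Published taxon-level isotope means for the outlet-channel food web."""
    with _FIXTURES.joinpath("table2_isotopes.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        IsotopeSample(
            taxon=row.taxon,
            d13c=row.d13c,
            d15n=row.d15n,
            d13c_sd=None if pd.isna(row.d13c_sd) else row.d13c_sd,
            d15n_sd=None if pd.isna(row.d15n_sd) else row.d15n_sd,
        )
        for row in df.itertuples()
    ]


def foodweb_pairs(with_printed: bool = False):
    """The published consumer/diet pairings.

    Returns (consumer, reference) tuples, or the full DataFrame including
    the printed Δ values when ``with_printed`` is set.
    """
    with _FIXTURES.joinpath("table2_pairs.csv").open() as fh:
        df = pd.read_csv(fh)
    if with_printed:
        return df
    return list(zip(df["consumer"], df["reference"]))


def headline_loads() -> tuple[float, float]:
    """(input, output) seasonal N loads (t) bracketing the lagoon, 2018."""
    return HEADLINE_INPUT_N_T, HEADLINE_OUTPUT_N_T
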