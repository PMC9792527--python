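"""Stable-isotope trophic arithmetic for the outlet-channel food web.

Carbon and nitrogen stable-isotope ratios are expressed as per-mil (‰)
deviations from international standards (δ¹³C, δ¹⁵N). A consumer is
enriched relative to its diet by a roughly constant trophic fractionation
(discrimination) per level — conventionally 3.4‰ for nitrogen and 0.4‰ for
carbon — which makes δ¹⁵N offsets a ruler for trophic position:

    TP = λ + (δ¹⁵N_consumer − δ¹⁵N_base) / Δ¹⁵N

with λ the trophic level of the baseline organism (2 for a primary
consumer such as an amphipod).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "IsotopeSample",
    "FractionationConstants",
    "fractionation",
    "trophic_position",
    "fractionation_table",
    "biplot_table",
]


@dataclass(frozen=True)
class FractionationConstants:
    """Per-trophic-level isotope enrichment (‰): 3.4 for N, 0.4 for C."""

    delta_n_per_level: float = 3.4
    delta_c_per_level: float = 0.4

    def __post_init__(self) -> None:
        if self.delta_n_per_level <= 0:
            raise ValueError("delta_n_per_level must be > 0")


@dataclass(frozen=True)
class IsotopeSample:
    """Taxon-level isotope values: δ¹³C and δ¹⁵N means (‰) with optional
    dispersion (sd, ‰) and sample size."""

    taxon: str
    d13c: float
    d15n: float
    d13c_sd: float | None = None
    d15n_sd: float | None = None
    n: int | None = None
    reference_taxon: str | None = None

    def __post_init__(self) -> None:
        for name in ("d13c_sd", "d15n_sd"):
            sd = getattr(self, name)
            if sd is not None and sd < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")


def fractionation(consumer_delta: float, diet_delta: float) -> float:
    """Signed isotopic offset (‰) of a consumer over its diet: consumer − diet."""
    if not (math.isfinite(consumer_delta) and math.isfinite(diet_delta)):
        raise ValueError("inputs must be finite")
    return consumer_delta - diet_delta


def trophic_position(
    consumer_d15n: float,
    base_d15n: float,
    base_level: float = 2.0,
    constants: FractionationConstants = FractionationConstants(),
) -> float:
    """Trophic position from the δ¹⁵N offset over a baseline organism.

    ``base_level`` is the trophic level λ assigned to the baseline (2 for a
    primary consumer).
    """
    return base_level + fractionation(consumer_d15n, base_d15n) / constants.delta_n_per_level


def _index(samples: Sequence[IsotopeSample]) -> dict[str, IsotopeSample]:
    return {s.taxon: s for s in samples}


def fractionation_table(
    samples: Sequence[IsotopeSample], pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Δ¹³C and Δ¹⁵N offsets for each (consumer, reference) pair.

    When both members carry a standard deviation, a propagated dispersion
    sqrt(sd_consumer² + sd_reference²) is reported for the offset; otherwise
    the column is left missing.
    """
    by_taxon = _index(samples)
    rows = []
    for consumer, reference in pairs:
        for taxon in (consumer, reference):
            if taxon not in by_taxon:
                raise KeyError(f"taxon {taxon!r} not present in samples")
        cs, rs = by_taxon[consumer], by_taxon[reference]

        def _propagate(sd_a: float | None, sd_b: float | None) -> float | None:
            if sd_a is None or sd_b is None:
                return None
            return math.sqrt(sd_a**2 + sd_b**2)

        rows.append(
            {
                "consumer": consumer,
                "reference": reference,
                "delta_d13c": fractionation(cs.d13c, rs.d13c),
                "delta_d15n": fractionation(cs.d15n, rs.d15n),
                "delta_d13c_sd": _propagate(cs.d13c_sd, rs.d13c_sd),
                "delta_d15n_sd": _propagate(cs.d15n_sd, rs.d15n_sd),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "consumer",
            "reference",
            "delta_d13c",
            "delta_d15n",
            "delta_d13c_sd",
            "delta_d15n_sd",
        ],
    )


def biplot_table(samples: Sequence[IsotopeSample]) -> pd.DataFrame:
    """Plot-ready δ¹³C-vs-δ¹⁵N rows (taxon, means, error bars); no statistics."""
    if not samples:
        raise ValueError("no samples")
    return pd.DataFrame(
        [
            {
                "taxon": s.taxon,
                "d13c": s.d13c,
                "d15n": s.d15n,
                "d13c_err": s.d13c_sd,
                "d15n_err": s.d15n_sd,
                "n": s.n,
            }
            for s in samples
        ]
    )
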