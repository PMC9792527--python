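"""CSV/YAML/JSON readers and writers shared by the analysis modules.

Dialect: UTF-8, comma-separated, header row required, "." decimal; the day
column is an integer breeding-day index. Validation errors name the
offending column or line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .budget import ScenarioSpec
from .datasets import scenario_from_dict
from .load import OutletRecord

__all__ = [
    "read_outlet_csv",
    "write_outlet_csv",
    "read_scenario_yaml",
    "write_scenario_yaml",
    "write_json_report",
]

_OUTLET_COLUMNS = ("day", "discharge_lps", "concentration_mgl")


def read_outlet_csv(path) -> list[OutletRecord]:
    """Read a daily outlet series from CSV.

    Requires columns day, discharge_lps, concentration_mgl; raises on a
    missing column (naming it) or an invalid row (naming its line number,
    header = line 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _OUTLET_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if df.empty:
        raise ValueError(f"no records in {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            records.append(
                OutletRecord(
                    day=int(row.day),
                    discharge_lps=float(row.discharge_lps),
                    concentration_mgl=float(row.concentration_mgl),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid record at line {line} of {path}: {exc}") from exc
    return records


def write_outlet_csv(path, series: Sequence[OutletRecord]) -> None:
    # %.17g keeps the write-read round trip bit-exact
    pd.DataFrame([vars(r) for r in series]).to_csv(path, index=False, float_format="%.17g")


def read_scenario_yaml(path) -> ScenarioSpec:
    """Read a rearing scenario from a YAML mapping."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    return scenario_from_dict(data)


def write_scenario_yaml(path, scenario: ScenarioSpec) -> None:
    data = {
        "area_ha": scenario.area_ha,
        "loss_frac": scenario.loss_frac,
        "fcr": scenario.fcr,
        "name": scenario.name,
        "fractions": vars(scenario.fractions),
        "checkpoints": [
            {k: v for k, v in vars(cp).items() if v is not None}
            for cp in scenario.checkpoints
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_json_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
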