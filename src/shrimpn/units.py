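"""Unit conversions shared across the package.

All ledger masses are carried in metric tons; monitoring series use L/s for
discharge and mg/l for concentration. Conversions live here so that the
factor chain (mg/l x L/s x 86400 s/day x 1e-9 t/mg) is written exactly once.
"""

GRAMS_PER_TON = 1e6
SECONDS_PER_DAY = 86400.0
TONS_PER_MG = 1e-9


def grams_to_tons(grams: float) -> float:
    """Convert a mass in grams to metric tons."""
    return grams / GRAMS_PER_TON


def tons_to_grams(tons: float) -> float:
    """Convert a mass in metric tons to grams."""
    return tons * GRAMS_PER_TON


def flow_concentration_to_tons_per_day(discharge_lps: float, concentration_mgl: float) -> float:
    """Daily constituent mass flux past a cross-section, in tons/day.

    discharge_lps : channel discharge in litres per second
    concentration_mgl : constituent concentration in mg per litre
    """
    return discharge_lps * concentration_mgl * SECONDS_PER_DAY * TONS_PER_MG
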