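"""Estimate the seasonal nitrogen load leaving the outlet channel.

Generates a synthetic 120-day monitoring series (daily discharge and total-N
concentration with lognormal observation noise), estimates the seasonal
load by direct integration and by the seven-term rating-curve regression
with smearing correction, compares both against the generator's stored
truth, and reports the lagoon removal efficiency implied by the published
seasonal input/output loads.
"""

from shrimpn.datasets import headline_loads
from shrimpn.load import (
    direct_period_load,
    estimate_period_load,
    fit_rating_curve,
    seasonal_report,
)
from shrimpn.synthdata import OutletSeriesSpec, generate_outlet_series

series, true_load = generate_outlet_series(OutletSeriesSpec(noise_sigma=0.3, seed=42))
model = fit_rating_curve(series)

direct = direct_period_load(series)
regressed = estimate_period_load(model, series)
print(f"true seasonal load (noise-free latent): {true_load:7.2f} t")
print(f"direct integration of observations:     {direct:7.2f} t "
      f"({100 * (direct / true_load - 1):+.1f}%)")
print(f"rating-curve estimate (smearing bcf {model.smearing_factor:.3f}): "
      f"{regressed:7.2f} t ({100 * (regressed / true_load - 1):+.1f}%)")

report = seasonal_report(*headline_loads())
print()
print(f"published season: {report['input_load_t']} t N into the lagoon, "
      f"{report['output_load_t']} t N out -> {report['removal_pct']}% removed")
print()
print("Both estimators recover the true load to within a few percent at this")
print("noise level; the removal percentage is the share of the mass-balance")
print("input load retained or processed before the water reaches the wetland.")
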