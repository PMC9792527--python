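# shrimpn

Nutrient dynamics of shrimp-farm effluent: how much nitrogen and phosphorus
a coastal *Litopenaeus vannamei* grow-out site sends into its receiving
wetland, how the outlet concentration evolves over a breeding season, how
much of the load an artificial treatment lagoon removes, and what stable
isotopes say about who eats whom in the outlet channel.

The package is aimed at aquaculture-environment analysts: it turns a farm's
rearing schedule and outlet monitoring series into a defensible seasonal
nutrient budget.

## What it computes

**Mass-balance budget** (`shrimpn.budget`). Feed-borne nutrients at each
checkpoint day are partitioned as

    feed nutrient = unconsumed + retained (body) + excreted,

with nutrient mass fractions 6.5% N / 1.4% P in feed and 3% N / 1% P in
shrimp wet mass. The inorganic load to the environment is unconsumed +
excreted nutrient; per-hectare loads × farm area give site totals. Two
bookkeeping conventions are shipped: the published ledger convention
(`table1`, excreted = feed − retained) and a strictly mass-conserving one
(`strict`).

**Stock-and-flow simulator** (`shrimpn.dynamics`). A six-stock
system-dynamics model of pond nitrogen (individual N weight, count, total
discharged N, excreted, unconsumed and faecal stocks) advanced by explicit
Euler steps, with discontinuous mortality/harvest rules and an outlet
concentration `Ntotal / natural_current / 1000` reported in mg/l.

**Load estimation** (`shrimpn.load`). Seasonal constituent loads from daily
discharge Q (L/s) and concentration C (mg/l): direct integration
Σ Q·C·86400·10⁻⁹ t/day, and a seven-term rating curve

    ln L = a₀ + a₁ lnQ̃ + a₂ lnQ̃² + a₃ sin 2πT + a₄ cos 2πT + a₅ T + a₆ T²

(centered ln discharge and decimal time) fitted by OLS with Duan's smearing
factor correcting the log-retransformation bias. `seasonal_report` converts
an input/output load pair into a lagoon removal efficiency 1 − L_out/L_in.

**Isotope trophic arithmetic** (`shrimpn.isotopes`). Fractionation offsets
Δ = δ_consumer − δ_diet and trophic positions
TP = λ + (δ¹⁵N − δ¹⁵N_base)/3.4‰, with 3.4‰ (N) and 0.4‰ (C) per-level
enrichment.

**Synthetic data** (`shrimpn.synthdata`). Seeded generators for monitoring
series (exponential concentration ramp, late-season step increase,
lognormal noise), rearing scenarios and isotope food webs — each returning
its ground truth so every estimator has a recovery test.

## Worked example

```python
from shrimpn.budget import build_budget_table
from shrimpn.datasets import gomishan_scenarios
from shrimpn.dynamics import StellaParams, peak_concentration, simulate

table = build_budget_table(gomishan_scenarios()["2018"])
print(f"{table.site_n_total_t:.1f} t N, {table.site_p_total_t:.1f} t P")

day, peak = peak_concentration(simulate(StellaParams()))
print(f"grow-out peak {peak:.1f} mg/l on day {day:.0f}")
```

prints

```
220.5 t N, 39.1 t P
grow-out peak 280.4 mg/l on day 105
```

— the 830-ha season discharges ≈220 t of inorganic nitrogen and ≈39 t of
phosphorus toward the wetland, and the simulated outlet concentration peaks
at ≈280 mg/l when the stock reaches harvest weight. The `examples/`
directory has one narrative script per capability (budget ledger, season
simulation, load estimation, food-web isotopes); each prints its numbers
with a short interpretation. A thin CLI mirrors the library:
`shrimpn budget|simulate|load|isotope|synth|all --help`.

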