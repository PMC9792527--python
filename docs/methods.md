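# Methods

This note records the models, conventions and numerical choices behind
`shrimpn`, and what its synthetic-data tests do and do not demonstrate.

## Mass-balance budget

The budget is a static ledger evaluated at checkpoint days (defaults 50,
80, 110 of a ~4-month grow-out). Inputs per hectare are survivor density,
mean individual weight and cumulative feed; coefficients are the nutrient
mass fractions (feed: 6.5% N, 1.4% P; shrimp wet mass: 3% N, 1% P) and a
feed-loss fraction (0.30 for the 2018 scenario, 0.10 for 2021, inferred
from the monitored unconsumed/feed ratios).

Derived quantities: feed nutrient = feed × fraction; unconsumed feed =
feed × loss fraction; retained ("meat") nutrient = biomass × body fraction;
excreted nutrient; inorganic load = unconsumed + excreted; site total =
per-ha load × area.

Two excretion conventions are shipped because the published ledger and a
strict balance disagree:

* `table1` (default): excreted = feed − retained. This reproduces the
  published bookkeeping but counts unconsumed nutrient twice in the
  inorganic load (once as waste feed, once inside "excreted").
* `strict`: excreted = feed − unconsumed − retained, so
  feed = unconsumed + retained + excreted holds to machine precision.
  Negative balances (possible when monitored rows are inconsistent with the
  feed totals, as at the 2018 day-50 checkpoint for P) are clamped to zero
  with a warning.

Monitored rows (biomass, unconsumed feed) may be supplied per checkpoint
and then take precedence over the derived values; the packaged scenarios
carry the published monitored values, which are not exactly reproducible
from survivors × weight or feed × loss at the published rounding.
Reproduction tests compare computed cells to published ones within one unit
in the last printed digit, since the source table mixes rounding and
truncation. Site totals are compared at 1% relative tolerance; the
published totals themselves differ from their per-ha × area products by
~0.1–0.3%, and the published 2021 P total exists in two versions (10.7 and
16.12 t) of which only 16.12 t is consistent with the table's own per-ha
row — that value is used.

FCR (feed conversion ratio) is carried as scenario metadata only: the
published feed/biomass ratios (~1.45, ~1.35) do not equal the stated FCRs
(1.29, 1.22), so no row is derived from FCR.

## Stock-and-flow nitrogen model

Six stocks — individual nitrogen weight `ind_weight_N`, total discharged
nitrogen `Ntotal`, individual count `number`, cumulative excreted N,
cumulative unconsumed-feed N (`N_losses`) and cumulative faecal N
(`total_fecal`) — advance by explicit Euler: flows are evaluated at the old
state and all stocks updated simultaneously (standard system-dynamics
semantics). The auxiliary chain, implemented literally:

    ind_weight_B = ind_weight_N / 0.0285      body weight, g
    ind_food     = ind_weight_B × 0.03        daily ration
    biomass      = number × ind_weight_B × 0.2
    total_food   = biomass × ind_food × 1.287
    assimilation = ind_food × 0.16 × 0.3 × 0.9 × 0.5
    unconsumed   = total_food × 0.3 × 0.16 × 0.15
    faeces       = total_food × 0.3 × 0.16 × 0.85 × 0.1
    excretion    = total_food × 0.3 × 0.16 × 0.85 − (faeces + total_food × 0.3 × 0.16 × 0.85 × 0.25)
                 (algebraically total_food × 0.0408 × 0.65)
    mortality    = 0.01 × number if ind_weight_B < 20 else number
    harvest      = 0 if ind_weight_B < 10 else mortality × ind_weight_B
    Naccumulation = pond_number × excretion                       while harvest = 0
                  = pond_number × (excretion + total_fecal + N_losses)  once harvest > 0
    N_concentration = Ntotal / natural_current / 1000   (reported as mg/l)

Initialization is two-pass: auxiliaries are evaluated from the initial
nitrogen weight (0.027) and count before setting the dependent initial
stocks `N_excreted = 0.077 × total_food` and `total_fecal = 0.26 × ind_food`.
Note `total_fecal(0)` is per-individual and therefore nonzero even for an
empty pond; concentration nevertheless stays identically zero at zero
stocking because harvest = mortality × weight = 0 there.

Choices where the formulation is open:

* **dt and horizon.** dt = 1 day (conventional for a daily-ration model)
  and a 120-day horizon (the 4-month breeding season), both configurable.
  A refinement scan (dt = 1, 0.5, 0.25) moves the grow-out peak by ~1%
  (280.4 / 284.0 / 283.2 mg/l) with the first-order convergence pattern
  expected of explicit Euler.
* **Discontinuous rules.** The total-wipeout mortality rule at 20 g and the
  harvest switch at 10 g are implemented literally, with `number` clamped
  at ≥ 0; no smoothing.
* **Units.** The model mixes internal unit scales (the 0.2 biomass factor,
  the flow constant 140 given in L/s against channel geometry implying
  ~4300 L/s); stocks are carried in model units verbatim and only
  `N_concentration` is labelled mg/l, at the reporting layer.
* **Seasonal peak.** `Ntotal` is monotone non-decreasing, and once harvest
  begins the accumulation flow adds the accumulated faecal and feed-loss
  *stocks* every step, so the late-trajectory concentration grows without
  bound — a model artifact of the printed switch. The reported seasonal
  maximum is therefore the grow-out peak: the concentration accumulated up
  to harvest onset (day 105 at dt = 1; 280.4 mg/l at the 830 × 240,000
  configuration). `peak_concentration(..., phase="full")` gives the raw
  maximum instead.
* **Exact scaling.** `pond_number` and the initial count enter `Ntotal`
  only multiplicatively, so concentrations scale exactly with
  pond_number × init_number; the reduced-stocking run (1251 × 100,000) is
  forced to 0.628 × the full-stocking peak (176.1 mg/l). This scaling is a
  property of the equations, asserted by test.

## Load estimation

Daily load is Q·C·86400·10⁻⁹ t/day. The seasonal load is either the sum of
daily loads (direct integration; gaps > 1 day warn, optional linear
interpolation) or a rating-curve estimate for days without concentration
data. The rating curve is the classical seven-parameter form — intercept,
centered ln Q and its square, annual sine/cosine, centered decimal time and
its square — fitted by OLS on ln(load). Censored-data maximum-likelihood
machinery is deliberately out of scope (no censored values arise here); OLS
is transparent and exactly testable. Back-transformation uses Duan's
nonparametric smearing factor (mean of exp(residuals)), which corrects the
downward bias of exp(prediction) under multiplicative noise. Records with
zero discharge or concentration are excluded from fitting (count reported);
zero-discharge days predict zero load; regressors that are constant over
the usable records (e.g. ln Q under constant flow) are dropped and
reported. A minimum of 14 usable records is required for the 7-parameter
fit. Decimal time uses a 365-day year; the breeding period defaults to 120
consecutive days.

## Isotope module

Δ values are computed from taxon-level mean δ values only; where both
members of a pair carry a standard deviation the offset's dispersion is
reported as √(sd₁² + sd₂²) (an extension — the source table reports no
propagated uncertainty). The baseline trophic level λ defaults to 2,
appropriate for a primary-consumer baseline such as gammarid amphipods.
Group-significance annotations in the source table come from raw data that
is not available and are not recomputed. Bayesian mixing models and
lipid correction are out of scope.

## Synthetic-data generators

All generators are pure functions of their spec, seed included, and return
ground truth alongside the data.

* **Outlet series.** One reading per day (emulating a fixed-hour automated
  station) for a 120-day season. The latent concentration is a monotone
  exponential ramp (base 15 mg/l, rate 0.0175/day — tracking the roughly
  exponential growth of standing biomass) times a step increase (×1.5) from
  day 90 onward, reflecting the late-season surge in nitrogen output; the
  defaults put the latent end-of-season concentration near 190 mg/l, the
  scale observed at the real station. Discharge is a base flow (140 L/s)
  with a ±10% seasonal sinusoid plus 2% jitter, standing in for routine
  water exchange — not a hydraulic model. Observed concentrations carry
  multiplicative lognormal noise with unit mean, exp(N(−σ²/2, σ²)), σ = 0.3
  by default, so the latent series is the expectation of the observed one
  and the stored truth (exact integration of the latent series against the
  realized discharge) is the estimand of a mean-unbiased estimator.
* **Scenarios.** Exponential individual growth at the rate implied by the
  dynamic model's assimilation chain (≈0.0227/day), initial weight set so
  the final checkpoint reaches market weight 15.5 g; exponential survival
  at 0.002/day; cumulative feed = biomass × FCR.
* **Food webs.** Taxa at known trophic-level offsets above a baseline, δ
  values displaced by offset × (3.4‰, 0.4‰) and observed with Gaussian
  per-individual noise across n individuals.

What passing recovery tests show: the estimators are implemented correctly
and are statistically well-behaved under the generators' assumptions
(lognormal observation noise, in-family rating-curve structure, Gaussian
isotope noise). What they do not show: performance on the real monitoring
data, which has unknown noise structure, serial correlation, instrument
drift and off-season flows; the published seasonal measured loads are not
reproducible without that dataset and are used only where they enter the
published arithmetic (the 45% removal efficiency from the 220.157/121.8 t
pair).

## Numerical conventions

Masses in metric tons throughout the ledger; gram↔ton and
(L/s, mg/l)→t/day conversions centralized in `shrimpn.units`. CSV artifacts
are UTF-8, comma-separated, "." decimal, with floats written at %.17g so
write–read round trips are bit-exact (reading uses pandas' round-trip float
parser). Budget operations validate domains (non-negative masses, fractions
in range) and raise `ValueError` rather than silently clipping; the two
documented clamps (excretion balance, Euler count) warn.

## Known limitations

* The budget's `table1` convention double-counts unconsumed nutrient by
  construction; use `strict` for physically consistent balances.
* The dynamic model is single-cohort, deterministic, and dimensionally
  informal; its concentration output is meaningful up to harvest onset.
* The rating-curve estimator assumes uncensored, serially independent
  residuals; no AMLE, no multi-constituent support.
* Phosphorus has no dynamic model; the stock-and-flow model is N-only.
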