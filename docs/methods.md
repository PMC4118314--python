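# Methods

## Model structure

`osteosim` is a time-driven discrete event simulation with one-year
intervals. Each woman is simulated independently (no resource constraints,
no interaction) from her start age (50 or 75, start year 2009) until death
or the end of the interval in which she reaches 100. Within a year the
order of decisions is fixed:

1. **Osteoporosis onset** (average-risk women not yet osteoporotic), so
   incident osteoporosis affects the same year's fracture risk;
2. **Fracture draws**, one independent uniform per fracture type — several
   types may co-occur in one interval; an event fires when *u ≤ p*;
3. **Hospitalization** per acute fracture (femoral fractures always
   hospitalized), then **rehabilitation** given hospitalization;
4. **Nursing-home entry** (community women aged ≥ 65): fracture-related
   entry first, using the *highest* admission probability among the year's
   hospitalized fractures; otherwise background entry at the
   care-prevalence-derived rate. Entry is absorbing;
5. **Counterfactual background-NH draw** on a parallel track, used only by
   cost attribution;
6. **Survival**: life-table probability × residence RR × fracture RR, where
   the fracture RR is the maximum over in-window history entries with
   years-since buckets {fracture year, 2–5, 6–10}; wrist fractures carry no
   excess mortality; nothing persists beyond 10 years.

Fractures set the previous-fracture flag from the *next* interval on;
same-interval fractures do not count as "previous" for each other. A
preloaded prevalent fracture raises risk but carries no acute costs and no
excess mortality. Osteoporosis and NH residence are absorbing.

Two engines implement this flow: a per-woman reference engine
(`engine.py`) and a vectorized cohort engine (`cohort.py`). Both consume
the same counter-based Philox streams keyed by (seed, age, decision slot)
with the woman's index as stream position, and the test suite asserts they
produce identical histories. The keyed-stream design is also the
common-random-numbers (CRN) contract: paired cohorts that differ only in
risk group reuse every draw, so excess estimates are free of first-order
noise and are exactly zero under identical parameters.

## Calibration

All subgroup relative risks are derived so that the prevalence-weighted
subgroup average equals 1 exactly — the condition under which the
population-average simulated incidence reproduces the general-population
input probabilities:

* **Osteoporosis.** Femoral-neck T-scores are modeled as N(mean(age), 1);
  fracture risk scales as g^(−T) with g the gradient of risk per SD of
  BMD (age-dependent for hip, constant for other types). The osteoporotic
  subgroup (T ≤ −2.5) then has RR_OST = Φ(d + ln g)/Φ(d), d = −2.5 − mean,
  verified against numerical integration to < 1e-6. Prevalence is the
  implied Φ(−2.5 − mean), which keeps preload, onset incidence and the
  non-osteoporotic residue RR mutually consistent. RR_OST *increases* with
  the population mean T-score: in a healthier population the osteoporotic
  tail is more strongly selected.
* **Previous fracture.** The no-previous-fracture RR is the Schousboe
  residue 1/(1 + (RR_any − 1)·π). The prevalence π(age) is forward-solved
  self-consistently: first fractures arrive at rate
  (1 − Π_f(1 − p_f·RR_noPrev)), anchored at the published prevalence at 50.
* **Residence.** The community RR is the residue of the NH RR at the NH
  population share. The share is itself forward-solved under the
  differential mortality it implies, with background entry set to the flow
  that keeps the share on the (interpolated) care-prevalence ladder.

Derived calibration quantities are resolved per single year of age
(published inputs stay at their 5-year-band resolution, piecewise
constant). Band-resolution prevalences would drift within a band and break
the weighted identities at the ages the engine actually visits; the
identities hold to 1e-12 at every age, and in a world without differential
mortality the simulated age-class incidence reproduces the inputs within
binomial Monte Carlo error (tested at n = 30,000).

**Known limitation — mortality selection.** With fracture excess mortality
active, women with fractures, osteoporosis or NH residence die faster, so
their simulated prevalences at ages 90+ fall below the calibration
ladders and the simulated incidence in the highest age classes undershoots
the inputs (by roughly 10–30% beyond age 90 with the default placeholder
mortality RRs, < 5% below age 85). Real-world prevalence inputs absorb this
selection; a calibration that anticipates it would need a joint
deterministic companion model over (osteoporosis × recency of fracture ×
residence) and is out of scope.

## Costs

Costs are in EUR at the 2009 price level, booked at the end of the interval
of the triggering event and discounted at 3%/year (configurable) with a
whole-year exponent; "direct" totals comprise hospital, rehabilitation,
long-term care, outpatient, professional home care and informal care —
productivity losses (human-capital and friction-cost valuations) are
carried separately.

* Hospitalized fractures accrue the hospital unit cost (which bundles
  post-hospital outpatient aftercare) plus rehabilitation when drawn;
  non-hospitalized fractures accrue the outpatient-only cost. Professional
  home care and informal care attach only for community-dwelling women
  older than 65. Co-occurring fractures each accrue their own costs.
* **Fracture-attributable long-term care**: for fracture-caused NH entries,
  the yearly NH cost accrues from the entry year (weighted 0.5, the
  half-cycle correction) through the earlier of death and the year before
  the counterfactual background track would have institutionalized the
  woman. Background-caused entries accrue nothing. LTC euros attach to the
  NH episode, not to a fracture type, so by-type cost tables exclude them.
* **Productivity**: work absence per fracture before retirement (65) is
  employment rate × daily earnings × days lost, capped at the friction
  period under the friction-cost approach. Fracture-related deaths before
  65 (death within the excess-mortality window of a non-wrist fracture)
  cost the discounted earnings stream to retirement with a 0.5 first-year
  weight (human capital) or one friction period of earnings (friction
  cost). Earnings grow 2%/year.

Conservation properties (sector totals = grand total; by-type + LTC =
direct total; discounted ≤ undiscounted; zero unit costs ⇒ zero totals)
are asserted in the test suite on every representative run.

## Experiments

* **Base case**: 200,000 women per risk group by default, CRN-paired
  average-risk vs never-osteoporosis cohorts; reports lifetime counts,
  costs by sector and fracture type, attribution percentages and the
  annual cost-by-age curve (denominator: women alive at that age).
* **Scenarios**: the 18 combinations of start age {50, 75} × residence
  {community, NH (≥65 only)} × disease {O, avO, nO} × history {P, nP};
  the base case additionally draws the previous-fracture flag from
  prevalence.
* **Deterministic sensitivity S1–S20**: declarative transformations of the
  raw inputs (informal-care revaluation, mortality variants, CI bounds,
  ±30% prevalence/probabilities, hip-only NH admission, ±1–2%/year secular
  trends applied as (1+g)^(year−2009), 5% discounting). Each is rebuilt
  from raw inputs (recalibrating all derived quantities — except S6, which
  deliberately keeps the no-previous-fracture baseline so that removing the
  history risk factor is not a calibration no-op) and run against the
  same-seed base case; reported as % change of discounted direct excess
  cost.
* **PSA**: m = 1,500 outer parameter draws × 10,000 women per group by
  default (smaller in tests), beta for probabilities/prevalences, gamma for
  unit costs, lognormal for relative risks, moment-matched to the point
  value and the shipped 95% CI (else a CV of 0.2); draws are truncated to
  the feasible region by rejection; simulation streams are held fixed
  across draws so the spread is parameter uncertainty only; 2.5/97.5
  percentile intervals.
* **Internal validation**: modeled incidence = fractures / person-years at
  risk per age class in the average-risk population, against the input
  probabilities, plus the distribution of per-woman fracture counts.

## Parameters and provenance

Every parameter carries a provenance tag: `table1` and `table2` for the
printed fracture probabilities and unit costs, `paper_text` for stated
scalars (3% discounting, base year 2009, 2% wage growth, NH entry age 65,
T ≤ −2.5, femoral hospitalization 100%), and `placeholder` for values
published only in supplementary material. Placeholders sit at plausible
published magnitudes — e.g. a Gompertz life table with remaining life
expectancy ≈ 33 years at 50 for the 1959 birth cohort; fracture excess
mortality RRs of 3.5/2.0/1.5 (hip, by years-since bucket) declining with
age; hospitalization shares of 0.39/0.56/0.79/0.27 for vertebral, humerus,
pelvis and wrist fractures; a previous-fracture RR of 1.86 (1.75–1.98) —
and are isolated in the CSV tables written by
`osteosim write-defaults`, so transcribed values are a drop-in
replacement. Absolute cost and count levels depend on these placeholders;
the calibration identities, CRN properties and conservation invariants do
not, which is what the test suite pins down. Simulated results at the
shipped defaults (e.g. 0.18 lifetime hip fractures at average risk, ~49%
attributable) are therefore indicative, not estimates for Germany.

Default experiment sizes used by the shipped tests and the acceptance
script: 50,000 women for the closed-form Monte Carlo check, 200,000 for
internal validation, reduced smoke sizes (hundreds to thousands) for the
remaining experiment-layer tests; the engines simulate about 2.5 million
person-years per second on one core, so full-scale runs remain a matter of
seconds to minutes.

## Numerical choices

* Event rule "u ≤ p" exactly (boundary inclusive), per-type dedicated slots.
* Probabilities are clipped to [0, 1] after multiplying risk factors, with
  logged warnings on clipping.
* Age-class lookup is piecewise constant for published inputs; derived
  calibration arrays are single-year (band-midpoint linear interpolation
  for prevalence ladders).
* The Podgor–Leske conversion refuses decreasing prevalence ladders unless
  explicitly floored at zero (irreversibility).
* `rr_osteoporotic` raises on Φ underflow (threshold far below the mean)
  rather than returning garbage.
* Parameter validation collects all issues and reports them together.
* Seeds: master seed < 2^31; every stochastic quantity in engines,
  experiments and PSA derives from it.
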