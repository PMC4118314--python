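# osteosim

Discrete event simulation of the expected lifetime numbers and costs of
osteoporotic fractures in postmenopausal women, modeled on the German
healthcare setting.

`osteosim` is for health economists and epidemiologists who want
individual-level (first-order) estimates of the fracture burden
attributable to osteoporosis: it simulates women one by one from age 50 (or
75) to death or age 100 in yearly intervals, tracking six fracture types —
hip, other femur, clinical vertebral, humerus, pelvis, wrist — whose annual
probabilities depend on age, osteoporosis status, fracture history and
nursing-home (NH) residence, with state-dependent mortality, fracture-
triggered institutionalization, and cost accounting across hospital,
rehabilitation, long-term-care, outpatient, home-care, informal-care and
productivity sectors.

## The model in brief

An event of type *f* fires in a year when a uniform draw satisfies
*u ≤ p_f*, with

```
p_f(woman, age) = p_f^pop(age) · RR_osteo · RR_history · RR_residence
```

where `p_f^pop` is the general-population annual fracture probability and
the relative risks are **consistency-calibrated**: each risk factor splits
the population so that the prevalence-weighted average of the subgroup RRs
is exactly 1 —

* osteoporosis (T-score ≤ −2.5 at the femoral neck):
  `RR_OST = Φ(d + ln g) / Φ(d)` with `d = −2.5 − mean T-score` and `g` the
  gradient of risk per SD of BMD; `RR_noOST = (1 − π·RR_OST)/(1 − π)`;
* previous fracture: `RR_noPrev = 1 / (1 + (RR_any − 1)·π_prev)`, with
  hip- and non-hip-specific RRs applied on top for women with a history;
* NH residence: the community RR is the residue of the NH RR at the
  model-consistent NH population share.

Irreversible-state transition probabilities (osteoporosis onset, background
NH entry) come from prevalence ladders via the survival-ratio conversion
`q = 1 − ((1−p_high)/(1−p_low))^(1/span)`.

Attributable ("excess") quantities are estimated by simulating an
average-risk cohort and a never-osteoporosis cohort on **common random
numbers** — every decision has a dedicated random-stream slot keyed by
(seed, age, slot, person) — so the difference between the cohorts carries no
first-order Monte Carlo noise and is exactly 0 when the groups share
parameters. Fracture-attributable long-term-care costs use a parallel
counterfactual track: NH costs count only until the woman would have been
institutionalized anyway for background reasons.

The printed inputs (general-population fracture probabilities, 2009 unit
costs, discount rate 3%) ship exactly; inputs published only in
supplementary material ship as clearly flagged placeholder values
(`provenance="placeholder"`, editable CSVs via
`osteosim write-defaults`). Absolute cost levels therefore depend on
placeholders; the calibration structure, invariants and validation do not.

## Worked example

```python
import osteosim as om

params = om.default_parameter_set()
result = om.run_base_case(params, n=20_000, seed=1)
for ftype, avg in result.average.mean_counts.items():
    print(ftype, round(avg, 3), f"{result.excess.attribution_pct[ftype]:.1f}%")
```

prints (20,000 women per risk group, seed 1):

```
hip 0.183 48.7%
other_femur 0.023 42.5%
clinical_vertebral 0.141 31.6%
humerus 0.110 32.8%
pelvis 0.065 24.8%
wrist 0.194 14.7%
```

Each line is the expected number of fractures of that type over the
remaining lifetime of a 50 year old woman at average osteoporosis risk, and
the share of those fractures attributable to osteoporosis (they would not
occur in the paired never-osteoporosis cohort). The same run yields
discounted direct lifetime costs of €3,053 per woman, €1,113 of which is
osteoporosis-attributable excess, concentrated in the hospital (€501) and
long-term-care (€240) sectors — see `examples/02_excess_costs.py`.

The `examples/` directory holds one short script per capability: lifetime
fracture counts, excess costs by sector, the 18 start-characteristic
scenarios, deterministic sensitivity analyses S1–S20, and internal
validation. A thin CLI wraps the same functions:

```bash
osteosim run --n 200000 --seed 1 --out results/
osteosim sensitivity --id S13,S14,S20 --n 50000
osteosim validate --n 200000
osteosim write-defaults --out parameters/
```

## Layout

```
src/osteosim/
  parameters.py   inputs, calibration formulas, CSV I/O
  rng.py          keyed Philox streams (the CRN contract)
  engine.py       per-woman reference engine (scenarios, preload, yearly step)
  cohort.py       vectorized cohort engine (draw-for-draw identical)
  costs.py        cost attachment, LTC attribution, productivity, discounting
  experiments.py  base case, scenarios, S1-S20, PSA, internal validation
  fixtures.py     shipped defaults, random valid parameters, toy worlds
  cli.py          thin click front end
docs/methods.md   model description, assumptions, limitations
examples/         narrative scripts, one per capability
```
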