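# Methods

This note documents the model implemented in `strokecea`: its structure and
assumptions, every tunable parameter with its default and rationale, what
the synthetic-data generators do and do not emulate, the numerical choices,
and the known limitations.

## Model structure

The unit of analysis is a cohort of large-vessel-occlusion stroke patients
treated with endovascular thrombectomy (EVT), stratified by final
reperfusion pattern into strategy *arms*: near-complete/complete
reperfusion (eTICI 2c/3, also split into first-pass and multi-pass),
EVT-accessible incomplete reperfusion (eTICI 2b with a residual occlusion
reachable by further passes), and EVT-non-accessible incomplete
reperfusion. Arms differ only in their 90-day modified Rankin Scale (mRS)
outcome distribution and their IV-thrombolysis rate; everything downstream
(utilities, transition parameters, unit costs) is shared. This mirrors how
such decision models are built from trial strata: the arm's short-term
outcome distribution carries the whole treatment effect.

**Short-run phase (one 3-month cycle).** The cohort is placed on the arm's
90-day mRS distribution (mRS 6 = dead at 90 days maps to the absorbing Dead
state). Accruals: 0.25 years of utility-weighted survival; acute direct
costs (EVT procedure + IVT weighted by the arm's IVT rate + other acute
hospital costs + a quarter-year of state care costs); for the societal
perspective additionally a quarter-year of informal care and productivity
loss, and the premature-death earnings loss for the fraction dead by 90
days. The short-run phase is not discounted (it occupies time zero).

**Long-run phase (annual cycles to a lifetime horizon).** Seven states:
mRS 0–5 and absorbing Dead. For a living state `s` at age `a`:

- background mortality `q(a)` from the life table, scaled by an
  mRS-specific hazard ratio `HR_s` and capped at 1;
- an annual recurrent-stroke probability `p_rec` with case fatality `cf`;
- death combines the two causes multiplicatively (independence within a
  cycle): `P(death) = 1 − (1 − min(q·HR_s, 1))(1 − p_rec·cf)`;
- a non-fatal recurrence moves the patient to an equal-or-worse state drawn
  from a population post-stroke mRS distribution truncated at `s` and
  renormalized (mass staying at `s` folds into "remain"); the move
  probabilities are additionally scaled by survival of background
  mortality, `(1 − min(q·HR_s, 1))`, which makes rows exactly stochastic
  and guarantees that at the life table's terminal age (`q = 1`) every
  living state transitions to Dead with probability 1. A corollary is that
  the "remain" probability is never negative for any parameter combination
  in range, so the engine cannot produce an infeasible matrix from a
  validated parameter set.

The recurrence-worsening rule is deliberately a pluggable single vector
(`recurrent_mrs_dist`) rather than a full per-state matrix: per-state
post-recurrence data are rarely published, and the truncation construction
implements "deteriorate or die, never improve" without inventing numbers.

## Economic accounting

Two perspectives are accrued in the same pass:

- **healthcare**: acute costs plus `cost_annual_care[s]` per year alive in
  state `s`;
- **societal**: healthcare plus (i) `informal_care_cost[s]` per year,
  (ii) productivity loss `employment_rate(age) · (1 − return_to_work[s]) ·
  annual_wage` per year for survivors below retirement age, and (iii) a
  human-capital premature-death loss — the discounted sum of
  employment-weighted wages from the age at death to retirement age —
  booked as a lump sum in the cycle of death. Attributing the loss at death
  avoids tracking counterfactual survivor trajectories and is standard
  human-capital accounting.

All cost operations are linear in cycle length. With the default start age
of 70 (above the default retirement age of 65) the productivity and
premature-death components are zero and the societal–healthcare gap is
informal care alone; the components are fully exercised (and tested) at
younger start ages.

## Parameters and defaults

The default table (2021 USD) lives in `strokecea.synthetic.DEFAULT_PARAMETERS`
and is the table the generators write. Only the acute procedure costs are
published point estimates (EVT 15,510 USD; IV alteplase 7,421 USD); all
other defaults are conventional values a stroke cost-effectiveness analyst
would recognise, chosen once and documented here — they are *plausible
stand-ins*, not a transcription of any single published study's input
table, so absolute lifetime costs/QALYs from the defaults are not a
replication of any published point value.

| parameter | default | rationale |
|---|---|---|
| `mrs90_dist[arm]` | see module | ordered so complete reperfusion stochastically dominates the incomplete patterns and the accessible pattern fares worst; 90-day mortality 12–20 % |
| `utility[mRS 0–5]` | 1.0, 0.91, 0.76, 0.65, 0.33, 0.0 | utility-weighted-mRS convention |
| `p_recurrent_annual` | 0.04 | typical annual recurrent-stroke risk |
| `case_fatality_recurrent` | 0.16 | typical recurrent-stroke case fatality |
| `recurrent_mrs_dist` | 0.10…0.17 over mRS 0–5 | population post-stroke mRS mix, conditional on surviving the recurrence |
| `mortality_hr[mRS 0–5]` | 1.0, 1.2, 1.5, 2.0, 2.8, 4.0 | disability-graded long-term excess mortality |
| `cost_evt`, `cost_ivt` | 15,510 / 7,421 USD | published US estimates |
| `cost_acute_other` | 20,000 USD | US acute stroke admission beyond the procedure |
| `p_ivt[arm]` | 0.621 / 0.558 / 0.585 | observed arm-specific IVT rates |
| `cost_annual_care[mRS]` | 2k–45k USD/yr | disability-graded long-term care |
| `informal_care_cost[mRS]` | 0–26k USD/yr | unpaid family care priced per state per year (no hours×wage decomposition: hours data are not published) |
| `annual_wage` | 58,260 USD | US mean annual wage, 2021 |
| `employment_rate` | 5-year bands, 0.80→0.57 | labour-statistics granularity |
| `return_to_work[mRS]` | 0.85→0.0 | post-stroke return-to-work gradient |
| `retirement_age` / `start_age` | 65 / 70 | cohort mean age ≈ 70; one representative age, not an age mixture |
| discount rate | 3 %/yr | US panel convention; configurable incl. 0 |
| number of passes | does not change `cost_evt` | EVT priced as one procedure; multi-pass arms differ through outcomes, not procedure price |

Inflation indexing (`inflation_factor`, with an explicit `currency_year`)
is applied to all monetary fields at file-load time and the factor reset to
1, so a saved file is always internally consistent in its stated currency
year.

### PSA distributions

Each parameter carries a distribution spec; sampling is moment-matched
around the current point estimate, which keeps the spec file small and the
sample means centred (verified by test): Dirichlet for probability vectors
with effective sample size equal to the trial stratum (506 / 304 / 202 /
147 / 296; 450 for the recurrence vector), beta at 20 % relative SE for
probabilities and utilities (degenerate means 0 and 1 pass through
unchanged), gamma at 20 % relative SE for costs and wages, lognormal at
20 % for hazard ratios. Ages and the inflation factor are fixed. Each PSA
draw samples the full joint set once and runs both arms on it, so
incremental results retain parameter correlation.

## Synthetic data

`generate_cohort` draws patients with arm labels from a multinomial whose
defaults mirror a 1105-patient trial flowchart (45.8 % eTICI 2c3, 40.7 %
eTICI 2b split 147:296 accessible:non-accessible with 443/450 of 2b
angiograms assessable), ages ~N(70.7, 13.6²), 48.8 % female, and 90-day
mRS from arm-specific multinomials — sampled per patient, not quota-filled,
because that is how a trial cohort arises and it supports resampling
tests. `exact_flowchart_cohort` is the deterministic counterpart with the
reference stratum counts exactly, used for flowchart-accounting checks.
What is *not* emulated: angiographic images or the reading process (the
pattern is just a generated label), inter-rater variability, any covariate
structure linking age/sex/NIHSS to outcomes, and site effects. Passing
tests on synthetic cohorts therefore validate the accounting and the
estimator machinery, not the clinical realism of any particular rate.

`generate_life_table` uses a Gompertz hazard, `qx = 1 − exp(−a·e^{b·age})`
(defaults a = 2.5e-5, b = 0.095): smooth, age-increasing, two parameters —
the standard demographic stand-in for a national life table. The terminal
age (default 100) is forced absorbing.

## Numerical choices

- **Horizon.** Lifetime = run to and including the life-table terminal age;
  with `qx = 1` there the cohort is extinct at the end of the trace by
  construction. Default: start 70, terminal 100 → 31 annual cycles.
- **Cycle correction.** Default half-cycle (trapezoid of start/end
  occupancy); an end-of-cycle ("none") mode is provided because the choice
  shifts lifetime QALYs by roughly half a cycle's accrual and published
  models are often silent about it. The closed-form geometric-series tests
  pin both conventions exactly.
- **Discounting.** Cycle `t` (1-based) is discounted by `(1+r)^{−t}`; the
  3-month acute phase is treated as time zero and undiscounted. The
  premature-death lump sum is discounted inside itself (years from death to
  retirement) and then by the cycle factor.
- **Death-age attribution.** Deaths in cycle `t` are booked at integer age
  `start_age + t` (end of cycle); with annual cycles any within-cycle
  convention shifts the human-capital loss by under one year of wages.
- **Dominance classification** is by weak dominance: more QALYs at no
  greater cost (not both equal) ⇒ intervention dominant, mirrored for the
  comparator; strict trade-off quadrants get an ICER; exact ties are
  "equivalent". The boundary cases (equal QALYs, cheaper) have no defined
  ICER and weak dominance is the standard resolution.
- **Ties and degenerate inputs.** Probability-vector sums are enforced to
  1e-9; an all-dead 90-day distribution yields acute costs only;
  zero-utility and zero-hazard limits are exercised in tests.
- **Population-impact rounding.** "paper" mode rounds QALY components to
  integers and savings components to the nearest million *before* summing —
  the arithmetic printed reports actually use — while "exact" mode keeps
  full precision; increments are always computed unrounded internally.

## Verification strategy and problem sizes

The cohort engine is cross-checked against an independent microsimulation
oracle (inverse-CDF sampling of individual trajectories) at 40,000–60,000
patients, required to agree within 3 standard errors on QALYs and both cost
totals, on randomized parameter sets. Closed-form geometric-series limits
(horizon 1000, |error| < 1e-6), exhaustive row-sum and sign-quadrant
enumerations, and file-level recounts back the rest. The default PSA uses
10,000 draws; the acceptance script runs two full 10,000-draw PSAs in
roughly half a minute.

## Limitations

- Arm-level modelling only: no individual covariate effects on transitions.
- The default parameter table is a documented convention, not a transcribed
  study input table; absolute lifetime totals from the defaults are
  therefore illustrative, while structural results (dominance ordering,
  acceptability near 100 % vs the accessible pattern) are robust across the
  mode grid and the PSA.
- Procedural complication costs are not modelled separately; severe
  complications are assumed to surface through the 90-day mRS distribution.
- The human-capital approach values lost production as foregone earnings;
  no friction-cost alternative is provided.
- One representative start age; an age-mixture run can be approximated by
  weighting `run_lifetime` results over a cohort file's age distribution.
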