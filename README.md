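# strokecea

Markov cohort cost-effectiveness model of stroke outcomes after
endovascular thrombectomy (EVT), stratified by reperfusion pattern.

## The problem

EVT for large-vessel-occlusion ischemic stroke does not always achieve
complete reperfusion. The expanded Treatment In Cerebral Infarction (eTICI)
grade distinguishes near-complete/complete reperfusion (eTICI 2c/3) from
"successful but incomplete" reperfusion (eTICI 2b), and incomplete patterns
split further into those with a residual occlusion still *accessible* to
additional EVT passes and *non-accessible* patterns (small distal occlusions
or slow flow) that could only be treated pharmacologically. This package
quantifies the health-economic stakes of converting incomplete patterns to
complete reperfusion: lifetime quality-adjusted life years (QALYs) and costs
per strategy arm, incremental cost-effectiveness, parameter-uncertainty
analysis, and annual national totals.

It is written for health-economics and stroke-outcomes researchers who want
a reproducible, scriptable counterpart to spreadsheet- or GUI-built
decision models.

## The model

Each strategy arm (eTICI 2c3, accessible 2b, non-accessible 2b, single- vs
multi-pass 2c3) is simulated as a cohort through two phases:

1. **Short run (one 3-month cycle).** The cohort lands on the arm's 90-day
   modified Rankin Scale (mRS) distribution `π_arm` over states
   {mRS 0, …, mRS 5, dead}; acute costs (EVT 15,510 USD; IV alteplase
   7,421 USD weighted by the arm's IVT rate; other acute care) and a quarter
   year of utility-weighted survival are booked.
2. **Long run (annual Markov cycles to a lifetime horizon).** In each cycle a
   survivor in state `s` either stays, suffers a recurrent stroke and moves
   to an equal-or-worse state, or dies. The annual death probability is

   `P(death | s, a) = 1 − (1 − q(a)·HR_s)(1 − p_rec·cf)`

   with `q(a)` the life-table probability at age `a`, `HR_s` an
   mRS-specific hazard ratio, `p_rec` the annual recurrence probability and
   `cf` its case fatality. QALYs accrue as `Σ_s occ(s)·u_s` per cycle
   (half-cycle corrected by default) and are discounted at 3 %/year, as are
   costs.

Costs are accrued under a **healthcare** perspective (direct medical costs)
and a **societal** perspective that adds human-capital components: informal
care, productivity lost by survivors out of work, and earnings forgone
through premature death. Arms are compared by incremental costs and QALYs
(ΔC, ΔE), dominance classification, the ICER ΔC/ΔE when defined, and net
monetary benefit `NMB(λ) = λ·ΔE − ΔC` at willingness-to-pay thresholds of
50,000 and 100,000 USD/QALY. A probabilistic sensitivity analysis (PSA)
redraws every parameter from its distribution (Dirichlet for mRS vectors,
beta for probabilities/utilities, gamma for costs, lognormal for hazard
ratios) in 10,000 second-order Monte-Carlo draws.

No patient-level trial data are distributed: the `synthetic` module
generates trial-like cohorts, a Gompertz life table, and a complete default
parameter table with the published acute procedure costs, so the whole
pipeline runs self-contained. See `docs/methods.md` for every modelling
choice and default.

## Worked example

```python
from strokecea import MarkovCohortModel

model = MarkovCohortModel.from_defaults(
    intervention="etici2c3", comparator="etici2b_accessible")
results = model.fit()
print(results.summary())
```

prints

```
Markov cohort cost-effectiveness: base case
  intervention=etici2c3  comparator=etici2b_accessible
  discount=3.0%/yr  cycle_correction=half_cycle  currency: 2021 USD

       quantity    etici2c3  etici2b_accessible  difference                                    note
          qalys       5.678               4.216       1.463
cost_healthcare 143,564.227         155,783.907 -12,219.679
icer_healthcare         NaN                 NaN         NaN etici2b_accessible -> etici2c3 dominant
  cost_societal 204,664.773         226,001.370 -21,336.597
  icer_societal         NaN                 NaN         NaN etici2b_accessible -> etici2c3 dominant
```

Read: on the synthetic default inputs, achieving complete reperfusion gains
1.46 discounted lifetime QALYs over the EVT-accessible incomplete pattern
and *saves* about 12,200 USD (healthcare) / 21,300 USD (societal) per
patient, so it dominates — no ICER is reported for a dominant strategy.
`results.run_psa()` then yields the PSA scatter and acceptability, e.g.

```python
print(results.run_psa(n_draws=1000, master_seed=7).acceptability_table())
#   perspective       wtp  fraction_acceptable  n_draws
# 0  healthcare   50000.0                  1.0     1000
# 1  healthcare  100000.0                  1.0     1000
# 2    societal   50000.0                  1.0     1000
# 3    societal  100000.0                  1.0     1000
```

The same pipeline is scriptable from the shell:

```bash
strokecea simulate --n-patients 1105 --seed 1 --out-dir inputs
strokecea basecase --parameters inputs/parameters.json --life-table inputs/life_table.csv --out-dir out
strokecea psa      --parameters inputs/parameters.json --life-table inputs/life_table.csv --out-dir out
strokecea population --dqaly-accessible 1.14 --dqaly-non-accessible 0.45 \
    --dcost-accessible 6188 --dcost-accessible 9317 \
    --dcost-non-accessible 6156 --dcost-non-accessible 6473 --out-dir out
```

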