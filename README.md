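# strokecea

A decision-tree + Markov cohort cost-effectiveness model of intravenous
**argatroban added to standard therapy** versus **standard therapy alone** in
Chinese patients with acute ischemic stroke (AIS) who experience early
neurological deterioration (END), evaluated from the Chinese healthcare-system
perspective in 2023 CNY.  It is written for health-economics researchers and
HTA analysts who want a fully scripted, testable re-implementation of this
evaluation — every input, conversion, and analysis step is explicit and
re-runnable.

## The model

A short-term decision tree covers the first 3 months: the control arm's
month-3 modified Rankin Scale (mRS) distribution
p = (p₀, …, p₆) is reweighted category-wise by the trial risk ratios to give
the argatroban arm's distribution,

    p_i^arg = p_i RR_i / Σ_j p_j RR_j ,

and each arm accrues acute care costs (tiered by mRS 0–1 / 2–5 / death), the
priced sICH complication, and — in the intervention arm — the 220 mg drug
course plus infusion fees.

The month-3 distributions then seed a 7-state Markov cohort model
(states mRS 0–5 and dead) run for 119 quarter-year cycles (30-year horizon in
total).  Each cycle a patient can suffer at most one event: a recurrent stroke
(annual incidence R converted to a cycle probability via r = −ln(1−R)/4,
p = 1−e^(−r); fatal with per-event case fatality 0.21, otherwise the survivor
is spread uniformly over same-or-worse mRS states), or non-stroke death at the
age-banded background probability scaled on the rate scale by the
state-specific hazard ratio.  Costs and QALYs accrue per cycle and are
discounted at 5%/year; the incremental cost-effectiveness ratio
ICER = ΔC/ΔE is classified against willingness-to-pay thresholds of 1× and 3×
Chinese per-capita GDP (89,358 and 268,074 CNY/QALY).

Uncertainty is propagated three ways: a tornado (one-way) analysis over every
input's published range, a 10,000-draw probabilistic sensitivity analysis
(gamma costs, beta probabilities/utilities, lognormal risk and hazard ratios,
Dirichlet mRS distribution — all moment-matched to the published points and
95% ranges), and scenario analyses (drug price, start age, user-supplied life
tables).

## Worked example

```python
import strokecea as sc

params = sc.default_parameters()          # bundled published inputs
result = sc.run_base_case(params)
print(f"argatroban: {result.intervention.total_cost:,.0f} CNY, "
      f"{result.intervention.total_qaly:.2f} QALY")
print(f"control:    {result.comparator.total_cost:,.0f} CNY, "
      f"{result.comparator.total_qaly:.2f} QALY")
print(f"ICER: {result.icer:,.0f} CNY/QALY -> {result.classification}")
```

prints

```
argatroban: 130,903 CNY, 4.23 QALY
control:    128,585 CNY, 3.81 QALY
ICER: 5,564 CNY/QALY -> highly cost-effective
```

i.e. adding argatroban costs about 2,300 CNY more over a lifetime, gains about
0.42 QALYs (0.26 life-years), and at ~5.6 thousand CNY per QALY falls far
below the 1× per-capita-GDP threshold — argatroban is highly cost-effective.

The same analyses are available from a shell:

```sh
strokecea base                         # deterministic run + results table
strokecea owsa --plot                  # tornado over every ranged input
strokecea psa --n 10000 --seed 1       # probabilistic analysis, CEAC
strokecea scenario --drug-price 25.5   # highest-market-price scenario
strokecea simulate-trial --n-per-arm 314 --seed 7
```

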