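# Methods

## Model structure

Two hypothetical cohorts of Chinese AIS patients with early neurological
deterioration (median age 66) enter a decision tree that covers months 0–3:
randomization to argatroban + standard therapy or standard therapy alone
determines the month-3 mRS distribution, the acute-phase cost, QALYs and
life-years.  The month-3 distributions seed a 7-state Markov cohort model
(mRS 0–5 alive, mRS 6 dead) with quarter-year cycles run for 119 cycles, so
decision tree + Markov phase together span a 30-year horizon — effectively
lifetime for this cohort.  Transitions after month 3 depend only on health
state, never on the original treatment: the entire treatment effect is the
difference in the seeding distributions (and the arm-specific sICH pricing).

Assumptions inherited from the source evaluation and kept here:

- **One event per cycle.**  A patient either has a recurrent stroke, dies of
  a non-stroke cause, or remains stable within a cycle.
- **No spontaneous improvement.**  No transitions to lower mRS grades are
  parameterized; the constraint that a recurrence survivor cannot improve in
  the following cycle is therefore satisfied without tunnel states.
- **Recurrence redistribution.**  Survivors of a recurrence are spread
  uniformly over mRS states of the same or greater severity
  (weight 1/(6−j) from origin j).
- **sICH affects cost and utility only.**  The trial's mRS distributions
  already reflect every in-trial event; shifting states for sICH would double
  count.  The complication is priced (3,012 CNY) and carries a one-cycle
  utility decrement of 0.38 at the arm-specific probability (0.009 / 0.007).

## Event mathematics

- Annual incidence R → cycle probability: r = −ln(1−R)/4, p = 1−e^(−r).
  Applied to the recurrence incidence (0.112/year) and, for consistency (it
  is the only conversion formula the source states), to background mortality.
- Recurrence case fatality (0.21) is treated as a per-event probability, not
  an annual rate: only the recurrence incidence is flagged for conversion in
  the source, and "death after recurrent stroke" is event-conditional.  Its
  one-way range (0.189–0.232) covers the alternative readings.
- Hazard ratios multiply the background *rate*, not the probability
  (HRs are rate multipliers by definition; below age 85 the numerical
  difference is <0.1%).  Within a cycle, recurrence is evaluated first and
  non-stroke death applies to the non-recurring fraction, so row j of the
  transition matrix is: p_rec(1−cf)·uniform(j..5) + [p_rec·cf +
  (1−p_rec)·p_ns(age,j)]→dead + (1−p_rec)(1−p_ns) stays.
- Cohort age advances 0.25 years per cycle; the life-table band is looked up
  at the exact age at cycle start.  The last band (85−) is open-ended.

## Accrual and discounting conventions

Where the source is silent, the following conventions were chosen once and
are exercised by the reproduction tolerances:

- Cycle t = 1..119 is discounted at (1.05)^(−0.25t) (end-of-period
  convention); the decision-tree period is year 0 and undiscounted.
- **No half-cycle correction** (none is mentioned in the source; the effect
  is ≤2% here).
- Acute-phase QALYs use the month-3 distribution as the whole-period average;
  deaths in the tree accrue no post-hospitalization cost.
- Per Markov cycle, state costs (annual post-hospitalization costs × 0.25)
  and utilities are evaluated on end-of-cycle occupancy; each newly recurred
  patient incurs the 18,380 CNY event cost (decedents included — treatment
  precedes death) and survivors score the recurrence utility 0.42 *instead
  of* their state utility for that cycle.
- Life-years are reported discounted, mirroring the QALY arithmetic (the
  published incremental 2,459 CNY / 9,367 CNY-per-LY ratio implies a
  discounted ΔLY ≈ 0.26).
- Drug price 1.614 CNY/mg (the national median procurement price), which
  reproduces the published 355 CNY per 220 mg course; the tabulated 1.61 is
  the same number rounded.  Infusion administration adds the first-hour fee
  once plus 167 additional-hour fees (7-day continuous infusion) = 182.6 CNY.

## Distribution fitting for the probabilistic analysis

Every published range is read as a 95% interval, sd = (high−low)/3.92 — the
risk-ratio rows are printed 95% CIs and the same convention is applied
uniformly.  Families: gamma for costs, beta for probabilities and utilities,
lognormal for risk ratios and hazard ratios (location = ln point, so the
median is preserved exactly), Dirichlet for the control mRS distribution.
Beta and gamma parameters are moment-matched to (point, sd); fits preserve
the mean to well under 1% relative error.  Degenerate (zero-width) ranges
become point masses.  Boundary means (a probability of 0 or 1 with a nonzero
range, as for the sICH rows) are clamped to 1e−6 and the sd capped at 95% of
the feasible beta maximum.

The Dirichlet has a single concentration budget: each mRS category implies an
effective sample size nᵢ = mᵢ(1−mᵢ)/sdᵢ²; their across-category mean
(≈300 here, consistent with the source trial's arm size) scales the mean
vector into the concentration vector.

Background mortality and the discount rate carry no published range and are
held fixed in the PSA; the discount rate is still varied in the tornado over
its published 0–0.08 range.  Draws are jointly independent (no correlation
structure is published); each of the 10,000 draws gets its own spawned
substream of the master seed, so results are reproducible and
order-independent.  Per-category RR draws are renormalized through the same
month-3 reweighting as the base case, keeping every sampled distribution
proper.

The tornado varies every scalar input that carries a range (36 bars: 7 risk
ratios, 6 hazard ratios, 8 utilities/disutilities, 4 event probabilities,
10 costs, the discount rate), each to its low and high value with everything
else at the point estimate; the mRS distribution (a simplex, no scalar range)
and the life table are not varied one-way.

## Synthetic data

The generator emulates the summary inputs the model consumes: two-arm trial
outcomes with 314 patients per arm (the source trial's scale) — multinomial
mRS counts (treatment arm under the RR-weighted distribution) and binomial
sICH counts — from which proportions, per-category risk ratios with
delta-method log-scale 95% CIs, and sICH probabilities are re-estimated.
Zero cells get the Haldane–Anscombe correction (0.5 added to the four cells
of that category's 2×2) and are flagged.  `random_parameter_set` produces
structurally valid inputs (monotone utilities, non-decreasing hazard ratios,
rising life tables) for property tests.

What the synthetic path does *not* emulate: patient-level longitudinal
trajectories, within-trial covariate structure, or real-world cost
heterogeneity — passing tests show the estimation-to-decision pipeline is
internally consistent, not that the published trial estimates are correct.

## Numerical choices and degenerate inputs

- Transition-matrix rows sum to 1 to 1e−12 by construction; cohort mass is
  conserved to 1e−9 over all 119 cycles.
- ΔE = 0 makes the ICER undefined; classification then follows the sign of
  ΔC.  Negative ΔE with negative ΔC is classified by net monetary benefit at
  the 3× threshold.
- The month-3 reweighting renormalizes the product vector (Σ pᵢRRᵢ ≈ 1.0006
  at the published values — rounding noise in the printed CIs); the
  renormalizer is recorded for audit.
- Problem sizes used in the validation suite: the microsimulation oracle uses
  100,000 walkers; distribution-fit sampling checks use 50,000 draws;
  trial-estimation consistency runs up to 10⁶ patients per arm; the
  acceptance analyses use the full 119-cycle horizon and 10,000 PSA draws.

## Known limitations

- The recurrence risk is constant over time and states; the two death
  pathways are the only competing risks.
- The "less effective at the mRS 6 RR upper bound" behaviour reported for
  the source model is not reproduced under symmetric renormalization: extra
  deaths are offset proportionally across survivor categories, so the QALY
  gain shrinks but stays positive while incremental cost turns negative (the
  ICER still flips sign, via the numerator).  Reproducing a negative ΔE
  would require taking the extra deaths out of a specific survivor category,
  which would contradict the published tornado in other ways; the symmetric
  convention is kept.
- The PSA's joint parameter variance is fully determined by the published
  ranges and the independence assumption; summary fractions that depend on
  tail behaviour (probability of dominance, the exact highly-cost-effective
  percentage) are sensitive to unpublished sampling details of the source
  analysis.
- Sex-specific and start-age-60 scenarios run only with a user-supplied
  mortality table (the bundled table starts at age 66).
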