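# Methods

`capecea` implements a cost-utility analysis of one year of low-dose
capecitabine maintenance versus routine follow-up for women with early-stage
triple-negative breast cancer (TNBC) who have completed standard adjuvant
chemotherapy, from a Chinese societal perspective. This note documents the
model, its conventions, the synthetic-data generator, and the places where
the published inputs under-determine the analysis and a design choice had to
be made.

## Cohort model

A three-state Markov cohort — disease-free (DFS), relapse, death — is run in
monthly cycles from age 45 over a 30-year horizon (360 cycles). Everyone
starts disease-free; death is absorbing; relapsed patients cannot return to
DFS. Per-cycle transition probabilities are time-dependent:

* **DFS → death**: the age-specific background mortality of the general
  female population, converted from annual to monthly probability under a
  constant hazard within each year of age, `q_m = 1 − (1 − q_a)^(1/12)`.
* **DFS → relapse**: the DFS-curve exit probability
  `P(t) = 1 − S_dfs(t+1)/S_dfs(t)` minus `q_m`, floored at zero. DFS events
  comprise both relapse and death, so background deaths are netted out of
  the relapse inflow.
* **relapse → death**: configurable, see *Relapse mortality* below.

State occupancies are validated every cycle: non-negative, summing to one
within 1e-12, with the dead fraction non-decreasing.

### Survival inputs and the time-unit problem

Long-term extrapolation uses log-normal survival functions
`S(t) = 1 − Φ((ln t − μ)/σ)` fitted to the trial's individual-patient data.
The published location/scale pairs are (6.400, 0.908) and (5.437, 0.753)
for DFS and (6.074, 0.627) and (5.555, 0.505) for OS (maintenance /
observation respectively), but the time unit of `t` was never stated, and
no single unit reconciles all four pairs with the trial's printed 5-year
survival (the implied months-per-unit factor ranges from 2.4 to 4.3 across
curves). The default (`survival_input_mode: calibrated`) therefore keeps
each printed shape `σ` — a time-unit change `t → c·t` leaves `σ` invariant —
and re-anchors each location to the published 5-year Kaplan–Meier values
(DFS 82.8%/73.0%, OS 85.5%/81.3%) via the closed form
`μ' = ln 60 + σ·Φ⁻¹(S₅ᵧ)`. `as_printed` reads the table values on a months
axis instead. With multiple anchors the calibration is the probit-scale
least-squares solution and the residual survival-scale deviation is
reported.

### Relapse mortality (`relapse_death_mode`)

The published model description applies the same exit-probability formula to
the fitted curves but does not say how the relapse-state mortality was
parameterized. Two defensible constructions are implemented:

* **`os_formula`** (default): the exit probability of the fitted OS curve,
  `1 − S_os(t+1)/S_os(t)`, floored at background mortality. This is the
  formula-based reading of the model description. Its known weakness is
  that only relapsed patients experience the OS curve's attrition, so the
  model-implied OS runs above the fitted OS curve.
* **`os_matching`**: the fitted OS decrement `S_os(t) − S_os(t+1)` is
  decomposed each cycle into background deaths off the DFS compartment and
  relapse deaths, giving `p = (ΔOS − q_m·dfs)/relapse`, floored at `q_m`
  and capped at 1. The modeled OS then tracks the fitted OS trajectory by
  construction while the relapse pool lasts (the modeled 5-year OS matches
  the trial anchors to ~1 point), at the price of implausibly fast relapse
  mortality once the fitted OS curve dips toward the DFS curve.

Neither convention reproduces the published cost/QALY table; see
*Reproduction limits*.

## Economics

Costs (2020 USD at the fixed rate $1 = ¥6.4665) accrue on the occupancy at
cycle start; a half-cycle correction is available but off by default, which
matches the accounting the published totals imply most closely. Schedules:

* Drug ($306.48/mo) and safety monitoring ($46.83/mo) on DFS occupancy in
  cycles 0–11 of the maintenance arm only; routine follow-up is charged
  concurrently during that year (config-switchable, shifts the maintenance
  arm by ≈$450 undiscounted).
* Routine follow-up by time band: $38.39/mo before month 36, $21.32/mo for
  months 36–59, $12.78/mo thereafter. Productivity-time and travel costs
  use arm-specific first-year values ($49.97 vs $16.66; $12.37 vs $4.12 per
  month), shared band values afterwards; time costs stop at the statutory
  retirement age of 55 (cycle 120). The printed bands skip some intervals
  ("1–2 years" then "3–5 years"); each band is carried forward until the
  next printed band begins.
* Severe (grade 3/4) adverse events — hand-foot syndrome (incidence 13.45%,
  $15.46/case, disutility 0.12) and diarrhea (3.19%, $44.30/case, 0.10) —
  are charged once, in expectation, in the first cycle of the maintenance
  arm, as is their QALY decrement.
* Relapse treatment: $1546.43 per month of relapse occupancy
  (`relapse_cost_mode: occupancy`; a `per_case` lump alternative exists for
  scenario analysis).

Utilities are 0.8 (DFS), 0.73 (relapse), 0 (death); QALYs accrue as
utility-weighted occupancy divided by 12. Costs and QALYs are both
discounted at 5%/year with the compound monthly factor `(1.05)^(−t/12)`.
The incremental result reports Δcost, ΔQALY, the ICER with dominance flags,
and net monetary benefit at the willingness-to-pay threshold of $28,130 per
QALY (three times 2020 per-capita GDP).

## Sensitivity analyses

One-way analysis reruns the full pipeline with one entry at a time pinned to
its published range bounds (tornado ordering by ICER spread). The PSA draws
every entry per its published distribution class: gamma for costs and beta
for incidences, utilities and disutilities, each moment-matched with
mean = base value and SD = (high − low)/3.92 (the range read as a 95%
interval — the original hyper-parameterization is unstated, so this common
convention is used and is config-visible); transition probabilities get an
independent uniform ±5% multiplier per (arm, endpoint) applied to the
monthly exit probabilities — one multiplier per curve rather than 360
per-cycle perturbations, preserving curve coherence. The discount rate is
varied one-way (0–10%) but held fixed in the PSA, as published. Utility
draws are sampled independently, so a small fraction of PSA draws can have
u_relapse above u_DFS; base-case loading enforces the ordering. The ICER CI
is the 2.5/97.5 percentile of per-draw ICERs restricted to the positive
quadrant, with quadrant-crossing draws counted and reported.

## Synthetic trial generator

No individual-patient data are deposited, so the generator emulates the
source trial: 221/213 patients per arm, age ~ N(46, 9²) truncated to 24–70,
five categorical covariates with realistic prevalences, uniform 24-month
accrual and a 73-month administrative cutoff (median potential follow-up
61 months). Event times are log-normal with per-arm/endpoint marginals set
to the anchor-calibrated model curves, so the generator and the cohort
model describe the same population by construction. Covariates act through
a centered accelerated-failure linear predictor (log-time shifts ≤ 0.2 in
magnitude, variance ≈ 0.017 removed from the residual scale so the
marginals are preserved); DFS and OS share one standard-normal residual per
patient (comonotone coupling) and DFS is taken as min(DFS, OS), which keeps
both marginals exact wherever the DFS curve lies below the OS curve — in
particular throughout the censoring window — and guarantees
`dfs_time ≤ os_time` per record. A degenerate σ = 0 is allowed as a point
mass (useful for tests); σ < 0 is a configuration error.

What the generator does **not** emulate: dependent censoring or dropout
(the trial reported none), treatment discontinuation (excluded by design),
site effects, and any within-patient relapse→death process — the implied
joint distribution of relapse and death is the comonotone one, the least
structured choice consistent with the published marginals. Passing
calibration tests therefore show the pipeline recovers what the published
aggregates constrain, not that it would reproduce the real IPD.

## Number needed to treat

Adjusted absolute risk reduction at landmark times (12/24/60 months) uses a
Cox proportional-hazards model (Efron ties, Breslow baseline) with
treatment, age, menopausal status, tumor size, node status, Ki67 and
surgery type, standardized by g-computation: predicted risks are averaged
over the full cohort's covariate distribution with treatment forced to each
arm (a mean-covariate plug-in variant is available behind a flag).
NNT = 1/ARR when ARR > 0, otherwise flagged non-beneficial. Bootstrap CIs
refit the entire procedure on patient resamples; percentiles are taken on
the ARR scale and inverted, because the NNT scale is discontinuous at
ARR = 0 — an infinite upper bound signals a CI spanning the no-benefit
region. Cost per event prevented is NNT × incremental cost per patient.

## Numerical choices

* Parametric fits: exponential rate by its closed form; Weibull,
  log-normal, log-logistic and gamma by L-BFGS-B on log-scale parameters
  from method-of-moments starts, tolerance 1e-8 (deterministic).
* Model selection: candidates are ranked separately by AIC, BIC, −2LL and
  SSE against the KM step times; best mean rank wins, ties broken by AIC
  then name. The published criteria list does not state a combination rule;
  rank-averaging is the least arbitrary total order.
* Exit probabilities are clipped to [0, 1]; an exhausted curve (S = 0)
  exits with probability 1. Beyond the life table's last age the final
  annual probability is carried forward.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give identical records, PSA
  draws and bootstrap intervals.

## Reproduction limits

Two published results cannot be reproduced by any internally consistent
three-state model under the printed parameters, and the package does not
pretend otherwise:

1. **Arm-level totals.** Matching the observation arm's published 8.01
   discounted QALYs with the anchor-calibrated DFS curve requires roughly
   35 discounted months of relapse occupancy, which at $1546.43/month
   implies ≈$55k of relapse cost in that arm — an order of magnitude above
   the published $5714.96 total. Conversely, any construction that keeps
   relapse occupancy small enough for the published costs caps that arm
   near 6.2 QALYs. The default configuration reproduces the QALYs (9.42 vs
   9.30 and 7.70 vs 8.01) and correspondingly overstates the cost totals;
   the `os_matching`/`per_case` switches explore the other corner of the
   trade-off.
2. **ICER-derived quantities.** Because the incremental cost depends on the
   irreconcilable relapse-cost accounting, the default ICER (≈$4,410/QALY)
   sits above the published $2,630.53, and the CEAC's 50% crossing moves
   with it. The qualitative conclusions are unchanged: the ICER stays far
   below the $28,130 threshold under every one-way scenario, and the PSA
   probability of cost-effectiveness at that threshold is 100%.

Scaled problem sizes used by the test suite and the acceptance script —
10,000 PSA iterations, 200 generator replicates, 2,000-patient recovery
samples, bootstrap coverage at 40 × 300 resamples — were chosen as the
smallest sizes at which Monte-Carlo noise is comfortably inside the stated
tolerances.

## Known limitations

* The life table bundled under `data/` is a synthetic Gompertz
  approximation of 2020 Chinese female mortality (anchored at plausible
  adult rates), not the official table; it is config-replaceable and a
  minor ICER driver at these ages.
* Treatment interruption, dose modification and crossover are out of scope
  (the source trial reported 82.8% completion and the published model
  assumed full adherence).
* The ICERs of the four alternative survival distributions cannot be
  recomputed because their fitted parameters were not published; the
  distribution-selection machinery is exercised on synthetic data instead.
* Costs outside the published items (second-line specifics, non-travel
  non-medical costs) are not modelled.
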