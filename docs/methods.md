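# Methods

## Model structure

The model is a cohort-level (fraction-of-cohort) state-transition model with
a 1-month cycle, started at age 60 with the whole cohort in the
*Hospitalized HF* state (the index ADHF admission). Alive states:

* `hosp` — hospitalized for HF this month;
* `post1`, `post2` — tunnel states for the first and second post-discharge
  months (at most one cycle of occupancy per visit);
* `stable` — three or more consecutive non-hospitalized months, re-entered
  while event-free.

Absorbing states: cardiovascular death and non-cardiovascular death. The
hospitalized and tunnel months form the *vulnerable phase*: monthly
cardiovascular-death and readmission probabilities are elevated there, and
every death in that phase is counted as cardiovascular. Non-cardiovascular
(background) mortality applies only from the stable state, via an
age-banded life table (bands 60–64 … ≥85, monthly probabilities 0.0004 …
0.0054) shared by all strategies; age advances one whole year every 12
cycles, matching the table's resolution. Competing risks within a cycle are
additive: each exit probability is applied directly and the remainder goes
to the progression target (next tunnel state, or remaining stable). All
base-case sums are far below one, and validation rejects any parameter set
whose sums reach one.

To represent the late-initiation strategy the transient alive states are
duplicated into pre-switch and post-switch copies; the stable state is
always post-switch. Under late initiation the cohort takes enalapril
parameters in pre-switch states and sacubitril–valsartan parameters from
the first stable month onward, including later readmissions (no reversion):
treatment, once started, continues for life. The structurally simpler
memoryless alternative — sacubitril–valsartan parameters in the stable
state only, enalapril parameters during every vulnerable phase — was
implemented and compared during development; it shifts the late-initiation
ICER from about 3,816 to about 4,555 USD/QALY, and the no-reversion reading
was kept because it matches the stated treatment policy (drug continued
after discharge for the lifetime horizon). The two phase-uniform strategies
are unaffected by the duplication.

The lifetime horizon is realized as 480 cycles (age 60 → 100). Under
base-case mortality less than 1% of the cohort is alive at the end; the
residual mass is simply dropped, and the acceptance checks confirm the tail
is negligible.

## Parameter derivation

Cumulative trial proportions are converted to monthly probabilities under a
constant-rate assumption: rate = −ln(1 − e/n)/T per month, p = 1 −
exp(−rate). A treatment-effect hazard ratio is applied to the *event count*
before conversion (p = 1 − exp(ln(1 − hr·e/n)/T)), reproducing the source
derivation of the treated stable-phase readmission probability to the
printed fourth decimal; applying it on the hazard scale after conversion
would alter that decimal. Historical CNY costs are inflated along the
2015–2021 healthcare CPI chain (product 1.2335) and divided by the 2021
exchange rate 6.4515 CNY/USD. The annual discount rate is the geometric
mean of the CPI chain minus one (0.0304, worked at the rounded 0.03 in the
base case). The enalapril-arm vulnerable-phase inputs have no published
count derivation and enter as terminal values.

## Accrual conventions

Two accrual channels, reported separately and summing exactly to the
totals:

* **Occupancy accruals** — monthly medication/standard-care cost, monthly
  utility, and life-years (1/12 per alive month). These use the trapezoidal
  half-cycle correction (average of consecutive occupancy rows) and a
  mid-cycle discount factor (1+r)^(−(t+0.5)/12).
* **Event accruals** — the hospitalization cost (2,361.5 USD) and utility
  decrement (−0.1 QALY) per admission, index admission included, discounted
  at the start of the admission cycle, (1+r)^(−t/12).

Three structural conventions were fixed by reconciling the published
decomposition of totals rather than by any explicit statement in the source
text, which leaves them open:

1. the sacubitril–valsartan monthly price (50.5 USD) is *added on top of*
   the bundled enalapril-plus-standard-care cost (37.9 USD) when the drug is
   active — the published treated-arm occupancy cost is consistent with
   ~88.4 USD per non-hospitalized month, not 50.5;
2. no monthly medication/standard-care cost accrues during hospitalized
   months (the per-event admission cost covers inpatient care);
3. utility and life-years accrue in every alive state, hospitalized months
   included, at the active drug's monthly utility.

Reported life-years are discounted, matching the published convention.

## Economic endpoints

ICERs are computed on unrounded totals, with dominance classified before
division (dominant: cheaper and more effective; dominated: the reverse;
equal-effect comparisons yield no ratio). A strategy is cost-effective when
dominant or when its ICER is strictly below the willingness-to-pay
threshold, fixed at 37,654.5 USD/QALY (three times 2021 per-capita GDP,
242,928 CNY at 6.4515 CNY/USD). Net monetary benefit (wtp·QALY − cost)
drives the acceptability computations; its incremental sign flips exactly
at the pairwise ICER whenever the QALY gain is positive.

## Sensitivity analyses

**One-way:** each parameter with a published range (the fourteen
distributed parameters plus the discount rate, 0–0.06) is set to each bound
in turn, all else at base, and the early-initiation-vs-enalapril pipeline
is re-run; the tornado orders parameters by ICER-interval width. The life
table and starting age carry no ranges and stay fixed.

**Probabilistic:** each of the fourteen parameters with a published SD is
drawn independently — beta for probabilities and monthly utilities, gamma
for costs, moment-matched to (mean, SD); the admission disutility is drawn
as a beta on its magnitude and negated, since a beta cannot carry a
negative mean. The discount rate is excluded (no published SD). 10,000
draws run both cohort arms each; acceptability is the fraction of draws
with positive incremental net monetary benefit at the threshold.
Structurally invalid draws (competing probabilities reaching one, a utility
above one full month) are rejected and redrawn with a logged count — under
base-case hyper-parameters rejections essentially never occur, so no
truncation bias arises. Draws are *not* re-checked against the one-way
ranges: those bounds describe the deterministic analysis, and enforcing
them would truncate the distributions. The CEAC reports acceptability on a
0–50,000 USD grid (100 USD steps) and a bisection refines the 0.5-crossing
to 0.1 USD.

## Synthetic data and the micro-simulation oracle

The synthetic generator produces random parameter sets with the same shape
as the base case (valid probabilities, positive costs, utilities in
(0, 1/12]) under optional structural flags: vulnerable-phase risk above
stable-phase risk, and treated risk below (utility above) the reference
arm. It emulates the *structure* of plausible inputs, not any particular
population: passing property tests on generated sets demonstrates
engine-level invariants (conservation, monotonicity, valid pipelines), not
real-world calibration.

The micro-simulation oracle replays the identical transition rows patient
by patient with per-cycle categorical draws and accrues cost, QALY and
life-years with independently written per-patient code (trapezoidal
occupancy, event dating at admission cycles). Cohort expectations and the
mean of 10^6 simulated patients agree within 3 Monte-Carlo standard errors
on a 60-cycle horizon; the reduced horizon keeps the check fast while
exercising every state and both phases.

## Numerical choices and problem sizes

* One transition matrix per strategy and model year (the only age-dependent
  entry is background mortality), reused across the 12 cycles of that year.
* Trace rows sum to one within 1e−12 over all 480 cycles; absorbing
  occupancies are non-decreasing.
* Property tests that repeat Monte Carlo work (seed-to-seed agreement,
  synthetic pipeline runs) use a 120-cycle horizon; the oracle equivalence
  uses 60 cycles and the SE-scaling check 24. These sizes were chosen so
  each check still spans both phases and several life-table bands.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; PSA output is bit-reproducible for a fixed seed.

## Known limitations

* Inputs are summary statistics from two trials, a national cost study and
  a statistical yearbook; no patient-level heterogeneity or subgroup
  structure is represented.
* Adverse-event costs are excluded, and drug prices are constant over the
  lifetime horizon.
* PSA draws are independent across parameters; no correlation structure is
  available in the published inputs.
* The three accrual conventions above are reconstructions of an
  under-documented original implementation; the base-case checks therefore
  carry a ±15% band, and the early-initiation ICER lands within 2% of the
  published value while the late-initiation ICER sits ~14% below it (see
  the structural discussion above).
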