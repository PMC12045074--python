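# Methods

## Model structure and assumptions

The package implements a two-stage cohort model for TAVI (SAPIEN 3) versus
SAVR in severe symptomatic aortic stenosis at low surgical risk.

**Stage 1 — decision tree (first 30 days).** The cohort enters the model at
the procedure. Expected procedure cost per arm is

    index cost + rehab unit cost × rehab rate + pacemaker component,

where the pacemaker component is unit cost × insertion rate unless an
explicit expected-cost override is supplied. The bundled inputs carry such
an override for TAVI (1,139 SEK) because the published breakdown prints a
component that is inconsistent with its own unit cost and rate
(77,451 × 1.5 % = 1,162 SEK); the package reproduces the printed total and
documents, rather than resolves, the discrepancy. Thirty-day death,
disabling stroke and new AF are treated as mutually exclusive branches
(priority death > stroke > AF; their marginals must sum to ≤ 1) and fix the
day-30 state allocation. The remaining 30-day events (MI, TIA, bleeding,
AKI, non-disabling stroke) are cost-only: the patient returns to "alive and
well". In the base case these one-off AE costs are **excluded** from the
comparison; scenario 3 switches them on (`settings.include_acute_ae_costs`).
Thirty-day deaths accrue the one-off death cost once, reported under the
year-1 death-cost category.

**Stage 2 — Markov cohort (monthly cycles).** States: alive-and-well (AW),
treated AF, disabling stroke, dead (absorbing); no recovery transitions
(no AF→AW, no stroke→AW/AF). Cycle *t* is model month *t*+1; the trace is
seeded with the day-30 distribution at cycle 0 and the first month's
health-state costs and outcomes accrue there, while procedure and 30-day AE
costs belong to the acute result. Within a cycle, death is applied first
and the AF/stroke incidence probabilities act on the surviving residual
(rescaled proportionally if they ever sum above one — never by blind row
division). AW mortality is the sex-weighted life-table annual probability
at the current integer age converted to a monthly probability via
1 − (1 − p)^(1/12); AF and stroke occupants use 1 − (1 − p)^HR on the
monthly scale. The cohort ages deterministically; the sex mix is a fixed
weighting of the life-table probabilities, not separate strata.

**Accrual rules.**

* Health-state costs distinguish the first month in a state (incidence:
  new entrants this cycle) from subsequent months; caregiver costs for
  disabling stroke are added identically. AW monitoring costs differ
  between year 1 and later years.
* Rehospitalisation: expected cost = alive occupancy × monthly probability
  (years 1–3 schedule, then constant at the year-3 value) × unit cost.
* Reintervention is a cost-and-continue event: probability × the arm's
  full expected procedure cost (matching the published reintervention unit
  cost, which equals the whole procedure total), no state change. The
  `rr_reintervention` modifier scales the TAVI arm's probability.
* Pacemaker complications: the day-30 insertion probability defines a
  carrier fraction, which pays the monthly complication cost while alive
  (carrier status is independent of the state path).
* Death costs: one-off per incident death.
* QALYs: occupancy × (age-band population norm − state decrement)/12,
  decrement zero for AW; the decrement is an additive subtraction floored
  at zero. A multiplicative mode is deliberately not provided — additive
  decrements are how the source utilities are reported.
* Discounting: per-cycle factor (1 + r)^(−t/12), so annual boundaries hit
  the annual rate exactly; costs and outcomes have separate rates
  (both 3 % in the base case).

**Horizon.** "Lifetime" is operationalised as running to the life table's
terminal age (110), at which annual mortality is 1; finite horizons
(scenarios 4–8) truncate the cycle count. No half-cycle correction is
applied by default; `settings.half_cycle_correction` enables a simple
midpoint-occupancy correction for outcomes and is exercised in tests.

**Median survival** is read off the survival curve S((t+1)/12) = alive
fraction at cycle *t*, with S(0) = 1, linearly interpolated; an immortal
cohort reports "beyond the horizon" (`inf`).

## Key parameters

| Parameter | Default | Units / note |
|---|---|---|
| cycle length | 1 month | transitions are specified monthly |
| discount rate (costs, outcomes) | 0.03 / 0.03 | annual, per-cycle compounding |
| willingness to pay | 1,000,000 | SEK/QALY (500,000 as alternative threshold) |
| start age / male share | 75.0 / 0.5 | cohort midpoint of the 70–80 target group |
| hr_death_af | 1.46 | synthetic placeholder, meta-analysis magnitude |
| hr_death_stroke | 2.3 | synthetic placeholder |
| death cost | 30,000 | SEK, synthetic one-off end-of-life cost |
| PSA draws | 1,000 | Monte Carlo simulations |

All monetary values are whole SEK at the 2022 price level. Parameter files
are versioned YAML (`schema_version: 1`) with the life table in a separate
CSV (`age,sex,annual_mortality_prob`); unknown keys are hard errors because
a silently ignored typo would corrupt the ICER invisibly.

## Synthetic inputs: what they emulate and what they do not

The registry-derived inputs behind the original analysis (30-day event
probabilities, monthly transition probabilities, hazard ratios, utilities,
the national life table) are not public. The bundled base case therefore
pins every **published** cost input verbatim and fills the unpublished
quantities with fixed synthetic values chosen once so that the per-category
cost pattern (signs and orders of magnitude of the one-year and lifetime
breakdown rows) matches the published summary table: SAVR has the higher
30-day new-AF rate (0.21 vs 0.028) and first-year rehospitalisation rate,
TAVI carries the pacemaker burden, and long-run AF/stroke incidence is low
(monthly 1e-4 scale). The `synth` module can additionally sample whole
parameter sets from documented log-uniform ranges (listed in its module
docstring) for property testing, with the arm ordering preserved.

The synthetic life table is a Gompertz hazard h(a) = r·e^{s(a−75)} with
male level r = 0.031, slope s = 0.097 and a 0.65 female multiplier,
discretised to annual probabilities p = 1 − exp(−h); this yields a
remaining life expectancy at 75 of roughly 12–13 years, in the right range
for a general Swedish cohort, and is monotone in age by construction.

Consequently, passing tests demonstrate that the *machinery* is correct —
roll-ups, transitions, accrual, discounting, reporting, sensitivity
analyses, and exact agreement between the cohort engine and an independent
microsimulation — but the bundled base-case ICER is not, and cannot be, a
reproduction of the published headline ICER. The printed arithmetic
identities (procedure-cost roll-up; the incremental column as exact
differences of the printed per-arm values; the NMB/NHB implied by the
printed incremental cost and ICER) are reproduced exactly from printed
inputs.

## Verification strategy

The microsimulation (`microsim`) consumes the *same* per-cycle transition
matrices and per-cycle cost/utility inputs as the cohort engine and samples
individual state paths; costs conditional on the path are accrued
deterministically so that means are directly comparable while path
variability drives the standard errors. Equivalence of cohort expectations
and microsimulation means within ~3 standard errors at n = 100,000 is the
central correctness check; a failure would isolate an accrual bug rather
than a probability-construction bug, since probability construction is
shared.

## Numerical choices

* Row simplex is asserted to 1e-12 when matrices are built and occupancy
  conservation to 1e-9 over a full run (accumulated float error over ~430
  matrix-vector products).
* Rounding for reporting is half-away-from-zero to whole SEK; all
  consistency identities (additivity of the breakdown, NMB = ΔE(λ − ICER))
  are checked on unrounded values. The published-breakdown reproduction
  sums the rounded components, matching how the printed total was formed.
* Probability draws in the PSA are moment-matched from the base value with
  an assumed coefficient of variation of 0.2 (beta for probabilities and
  utility decrements, gamma for costs, lognormal for hazard ratios);
  parameters are drawn independently — no correlation structure is
  published, so none is invented. Monetary overrides are rounded to whole
  SEK (sub-SEK truncation is negligible at the 1e5 scale).
* DSA ranges default to ±20 % of base where no interval is available.
* ICER labels follow the CE-plane quadrants: "dominant", "dominated",
  "undefined" (ΔE = 0); the southwest quadrant reports savings per QALY
  forgone as a ratio.

## Scenario battery

Sixteen scenarios ship as a versioned YAML file: the discount ladder
(0 %/3 %/5 %, and 3 % costs with undiscounted outcomes), the horizon ladder
(5–30 years), removal of the AF survival penalty (HR → 1), zero AF state
costs, the AE-cost toggle, the late-postoperative-AF mortality HR of 5.1,
and alternative whole-procedure costs (277,327 / 243,462 SEK — applied by
replacing the index cost and zeroing the rehabilitation and pacemaker
components so the per-arm totals equal the quoted figures). Two scenarios
(alternative survival source; pooled SAPIEN 3/Ultra clinical inputs)
require inputs that are not public and ship as explicitly non-runnable
stubs.

## Known limitations

* No tunnel states beyond the month-1/month-2+ cost split; no structural
  valve-deterioration sub-model beyond the reintervention probability.
* 30-day adverse events carry no disutility (avoiding double counting with
  the state utilities), so quality-of-life differences in the first month
  are understated.
* The sex mix is a weighting, not a stratification; in a mixed cohort the
  twelve-monthly compounding of the weighted annual probability differs
  from compounding each sex separately by a second-order amount.
* Synthetic inputs reproduce structure and direction, not the registry's
  actual event rates; all base-case numbers should be read accordingly.

## Problem sizes used by the bundled analyses

The base case runs 432 monthly cycles (age 75 to the terminal age 110).
The PSA uses 1,000 draws, the microsimulation cross-check 100,000
individuals, and the test suite uses 20,000-individual microsimulations
and 30–40-draw PSAs for its statistical checks.
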