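# Methods

## Model

`cohortcea` implements a four-state Markov cohort model of adjunctive
treatment for pharmacoresistant focal-onset seizures. The states are
seizure free (complete response, CR), partial response (≥50% reduction in
seizure frequency), non-response, and discontinuation for any reason.
The cycle length is one trimester (90 days) and the default horizon is
8 cycles (~2 years, matching the licensing limit on brivaracetam use).
The cohort is treatment-naive at entry and realises its first multinomial
outcome at cycle 1, so the first occupancy row equals the per-cycle
outcome-probability vector. Per-cycle probabilities are held constant over
the horizon; there is no mortality state, no treatment sequencing after
discontinuation, and no half-cycle correction (occupancy is evaluated at
cycle end).

### Structural variants

The published inputs give one outcome-probability row per treatment but do
not state which states stop transitioning, and the published absolute CR
levels cannot be recovered from the rows alone (see *Known limitations*).
The package therefore exposes the structure as a config switch:

* `absorbing_sf_disc` (default): seizure freedom and discontinuation are
  absorbing; partial and non-responders re-draw each cycle. This matches
  the clinical reading of "discontinuation (any reason)" and keeps the CR
  outcome cumulative. Under this variant the ever-seizure-free share has
  the closed form `p_sf · (1 − (p_pr + p_nr)^n) / (1 − (p_pr + p_nr))`,
  used as an independent oracle in the tests.
* `absorbing_disc_only`: only discontinuation absorbs.
* `redraw_all`: every state re-draws each cycle.

`ever_sf` is computed as the first-passage probability into the
seizure-free state (the inflow from the never-yet-seizure-free pool), so
it is well defined and non-decreasing under every variant.

### Effectiveness outcome

The effect is the CR proportion, with three selectable readings of the
trace: `ever_sf` (default; cumulative first passage), `mean_sf_occupancy`,
and `terminal_sf`. No utilities or QALYs are modelled: the analysis this
package reproduces deliberately excluded them for lack of transferable
local preference data.

## Costing (payer perspective, JOD)

* **Drug cost**: daily dose × 90 days × per-mg price; the titration dose
  applies in cycle 1 and the maintenance dose afterwards. The wastage
  assumption — dose reductions earn no cost credit — is represented by not
  modelling any reduction pathway at all. Discontinued patients accrue no
  drug cost.
* **Service bundles per cycle**: seizure free and partial response get one
  neurologist visit (JOD 14) plus an EEG (JOD 100); non-response adds an
  emergency visit (JOD 30) and one inpatient night (JOD 100); discontinued
  patients get one outpatient visit only. Bundle contents are
  configurable; the defaults give 114 / 114 / 244 / 14 JOD per cycle.
* **Adverse events**: annual probabilities of ataxia, dizziness, fatigue,
  nausea, and somnolence are converted to per-cycle probabilities under a
  constant hazard, `1 − (1 − p)^(1/4)`. Every event triggers one GP visit
  (JOD 8); ataxia is managed with acetazolamide and dizziness/nausea with
  cinnarizine. The management regimen (mg/day × days) is not published;
  the default is a typical adult daily dose (500 mg acetazolamide, 75 mg
  cinnarizine) for the full 90-day cycle, consistent with the wastage
  scenario's conservatism, and fully configurable. AE costs accrue every
  cycle for the non-discontinued fraction (accrual restricted to the first
  year is available via `ae_accrual: first_year`); discontinued patients
  are off drug and accrue no AE cost.
* **Doses**: the published analysis priced drugs from median daily doses
  in a supplement that is not part of the main text. Doses are therefore
  mandatory config inputs. The shipped defaults (BRV 50/100, ESL 400/800,
  LCM 100/400, PER 2/8 mg/day titration/maintenance) come from the
  products' label ranges and are marked as assumptions in the config file.
* **Discounting** is year-stepped per the stated rule: cycles in the
  second model year are discounted by one year at 3.5% (no per-cycle
  compounding); year-1 flows are undiscounted. No inflation adjustment
  over the 2-year horizon.

## Incremental analysis

Pairwise only, with the reference treatment (BRV) against each
comparator. `ICER = ΔCost / ΔEffect` with the effect difference on the
proportion scale; the resulting number is reported under the field's
"JOD per 1% CR" label, the convention that reproduces the published
worked-example ratios (−214 / 0.2901 ≈ −738). Dominance is classified by
the signs of (ΔE, ΔC): cost-saving (south-east; the dominant class),
north-east trade-off, dominated (north-west), south-west trade-off. A zero
effect difference makes the ICER undefined and raises an error carrying
the cost-difference sign. Net monetary benefit is `WTP × effect − cost`
on the same scale; the default willingness-to-pay threshold is JOD 9000
(three times Jordanian GDP per capita).

## Probabilistic sensitivity analysis

Second-order Monte Carlo, default 2000 iterations, seeded and
bit-reproducible. Parameter distributions are moment-matched:

* **Probabilities** (transition, adverse event): beta with
  `alpha = m·k`, `beta = (1−m)·k`, `k = m(1−m)/se² − 1`. For each
  treatment the seizure-free, partial-response, and discontinuation
  probabilities are drawn from their betas and non-response is the simplex
  residual; negative residuals are rejected and redrawn (capped at 1000
  attempts). Adverse-event probabilities carry no published SE; they use
  the same ±25% convention as costs (SE = 0.25·mean/1.96), configurable
  via `ae_probability_pct`.
* **Costs**: gamma with `shape = m²/se²`, `scale = se²/m`. Per-mg drug
  prices use their published SEs; service costs translate the stated ±25%
  range into an SE of `0.25 · mean / 1.96` (the range read as a 95%
  interval half-width).
* **Discount rate**: beta affinely rescaled to the stated 0–5% range,
  moment-matched to mean 3.5% with SE 0.00625 (a quarter of the
  half-range), honouring both the stated family and the stated range.

Parameters are sampled independently (no correlation information is
published); doses are not varied (no SE exists for them). An SE of zero
degenerates to a point mass without consuming random numbers, so a
zero-SE PSA reproduces the deterministic pipeline exactly, iteration by
iteration — a property the tests assert bit-for-bit.

Plane quadrant tallies use the tie rule ΔC = 0 → cost-saving side,
ΔE = 0 → non-effective side. The CEAC reports, per willingness-to-pay
value and comparator, the fraction of iterations in which the reference
treatment's net monetary benefit exceeds the comparator's.

## Synthetic data and oracles

`cohortcea.synthetic` generates fully valid random model configurations:
transition profiles from a symmetric Dirichlet (concentration 8 by
default, keeping residual non-response probabilities safely positive),
SEs as a fraction (default 0.05) of the binomial bound `sqrt(p(1−p))` so
beta feasibility always holds, log-uniform per-mg prices, and uniform
annual AE probabilities. The microsimulation oracle propagates individual
agents (default checks use 10⁵) through the same transition structure and
returns empirical occupancy with binomial standard errors; the cohort
expectation model is required to agree within 3 SEs per state per cycle.
What the generator does not emulate: correlation between parameters,
patient-level heterogeneity, and time-varying transition probabilities —
so passing tests validate the pipeline's arithmetic and sampling logic,
not the clinical realism of any particular input set.

## Numerical choices

* Simplex validation tolerance 1e−6 on input (printed rows sum to 1
  exactly); deviations below it are renormalised silently, above it raise
  naming the treatment. Internally, occupancy rows must sum to 1 within
  1e−12 at every cycle.
* ICERs are reported to the nearest JOD, effects to two decimal
  percentage points, JOD amounts to two decimals in report files and full
  precision in iteration files.
* Problem sizes in the test suite: 10⁵ agents for microsimulation
  cross-checks, 10⁵ draws for sampler moment recovery, 2000 iterations
  for PSA-level checks — the package's standard validation sizes, all of
  which run in seconds.

## Known limitations

* The published absolute cost and CR levels (e.g. 57.71% CR for BRV)
  are not reproducible from the main-text inputs: the dose schedule lives
  in an unavailable supplement and the published cumulative CR values
  imply additional model structure (such as post-discontinuation
  pathways) beyond the printed per-cycle rows — under the default variant
  the BRV rows yield an ever-seizure-free share of ≈ 21.8%, and ≈ 42%
  under `redraw_all`. The package does not tune toward the printed
  levels; it reproduces the incremental worked examples exactly from the
  published pairs and validates everything else by construction. The
  published PSA ICERs inherit the same dependence and are likewise
  documented rather than targeted.
* No efficiency frontier across all four treatments (the analysis is
  strictly pairwise), no EVPI, no budget impact, no societal costs.
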