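# Methods

`crcscreen` is a desk-scale comparative- and cost-effectiveness pipeline for
blood-based colorectal cancer (CRC) screening.  It answers one question: what
accuracy, screening interval and price would a blood test need to match the
effectiveness and value of the established alternatives — annual fecal
immunochemical testing (FIT) and decennial colonoscopy — for an average-risk
cohort entering screening at age 45?

The pipeline has five stages: a synthetic adenoma–carcinoma natural-history
microsimulation, a screening-strategy overlay, a cost-effectiveness engine,
a 900-scenario factorial threshold analysis, and a scenario-discovery step
(random-forest variable importance plus a smoothed net-monetary-benefit map).

## Natural-history model

One configurable stand-in model generates screening-free life histories in
continuous time.  It is deliberately simple: published comparative analyses
of CRC screening rest on large, independently calibrated microsimulation
models whose internal equations are not public; what the downstream analysis
actually requires is the *qualitative* structure of the adenoma–carcinoma
sequence plus a calibration anchor, and that is what this module provides.

Structure per person:

* **Heterogeneous adenoma risk.** A lognormal frailty `Z` with unit mean and
  log-SD `adenoma_risk_dispersion` (default 1.1) multiplies the adenoma
  onset process.  Most people develop no adenomas; a minority develop
  several — lifetime adenoma prevalence under the defaults is ~63%.
* **Onset.** Adenomas arise from a non-homogeneous Poisson process with
  cumulative hazard `rate · Z · (a / 100)^k` (shape `k = 2.6`), i.e. onset
  density rising as a power of age.  `baseline_onset_rate` (default 1.96, the
  shipped calibration — see below) is the expected lifetime adenoma count
  for a frailty-1 person.
* **Progression.** Each adenoma independently dwells non-advanced for a
  lognormal time (median 25 y, log-SD 0.7) before becoming advanced
  (≥ 10 mm, represented categorically).  An advanced adenoma progresses to
  preclinical cancer with probability 0.40 after a lognormal dwell (median
  11 y, log-SD 0.8); the preclinical (screen-detectable, asymptomatic)
  cancer surfaces clinically after a lognormal sojourn (median 4 y, log-SD
  0.5).  These dwell/sojourn families and moments are calibration targets,
  not literature values: they are chosen so that screening's detectable
  window and the age profile of incidence (mean clinical diagnosis near age
  73) are plausible, then the onset rate is calibrated (below).
* **Stage and survival.** Detection draws a two-stage (early/late) label:
  screen detection uses an early fraction of 0.78, symptomatic detection
  0.42 — the stage shift is the entire mortality benefit of detecting an
  existing cancer.  Survival after detection is a per-stage cure fraction +
  exponential: early stage dies of CRC with probability 0.15 (mean 6 y to
  death), late stage 0.78 (mean 2.2 y).  One primary cancer per person;
  subsequent clinical cancers are ignored.
* **Competing mortality.** Other-cause death comes from an annual life table,
  by default a Gompertz–Makeham hazard (A = 3.4e-4, B = 2.4e-5, θ = 0.094,
  q = 1 at age 100) fitted so remaining life expectancy at 45 is ≈ 37 years,
  matching a modern US cohort.  Any `age,q` CSV can be substituted.
* **Average-risk entry.** Persons whose screening-free history would include
  a symptomatic CRC diagnosis before 45 are resampled within their own
  random substream (< 1% of draws), conditioning the cohort on no CRC
  history at entry.  Prevalent adenomas and preclinical cancers at 45 are
  retained — they are what the first screen can find.

**Calibration.** `calibrate_defaults` bisects on a multiplier of
`baseline_onset_rate` (extending the bracket geometrically when needed)
until simulated lifetime CRC deaths per 1000 unscreened 45-year-olds fall in
a target interval.  The shipped default (rate 1.96) was produced this way
against the 32–36 per 1000 envelope at n = 200,000 and gives ≈ 33–35 deaths
and ≈ 74–77 clinical cancers per 1000 across seeds, with an unscreened
discounted CRC-care cost near $5,200 per person.

## Random-number architecture

Every draw is keyed, not sequential: a splitmix64-style hash of
`(seed, stream, person, context…)` yields per-event uniforms, and a Philox
generator keyed the same way supplies per-person bulk draws.  Consequences:

* person *i*'s history does not depend on cohort size — a 100-person cohort
  is a prefix of a 1000-person cohort at the same seed;
* strategies share natural histories *and* overlay draws at identical exam
  ages (common random numbers).  A strategy with higher sensitivity turns a
  superset of the same screens positive; detection, stage and survival
  uniforms are shared person-level, so contrasts between strategies are
  pathwise paired.  This is why an inert test (sensitivity 0, specificity 1)
  reproduces the unscreened life course *exactly*, and why QALY-gained
  curves are monotone in sensitivity at desk-scale n rather than only in
  expectation.  The stage uniform maps to a weakly earlier stage under
  screen detection and the survival uniform to a weakly longer survival in
  the earlier stage, so screen detection never worsens an individual cancer
  path.

## Screening overlay

Noninvasive tests (FIT, blood) are person-level: positivity depends on the
most advanced lesion present — CRC sensitivity against preclinical cancer,
advanced-adenoma sensitivity against advanced adenomas, `1 − specificity`
otherwise.  A positive in a person with any adenoma counts as a true
positive: a false positive exists only when follow-up colonoscopy finds
nothing.  Colonoscopy is lesion-level (default sensitivity 0.91 per adenoma
and per cancer, specificity 1.0): each lesion is detected independently,
detected adenomas are excised and their future progression cancelled.

Regimen state machine (full adherence assumed): routine screens every
`interval` years from 45 through 75; any positive noninvasive test triggers
an immediate follow-up colonoscopy; adenoma findings move the person to
colonoscopy surveillance until 85 (high-risk — ≥ 1 advanced or ≥ 3 adenomas
— every 3 y; low-risk every 7 y; a negative surveillance exam next at 10 y);
a clean colonoscopy after a false-positive resumes the routine regimen 10
years later.  A screen-detected cancer ends screening; a symptomatic cancer
additionally incurs one diagnostic colonoscopy.  The surveillance intervals
and FIT specificity (0.964) are documented placeholder values in the spirit
of US guidelines, configurable in `RunConfig`.

Costs: per-test unit costs (FIT $23.42, blood $500 base case), colonoscopy
$963.95 without / $1,312.36 with polypectomy, complications (probability
0.0025 per procedure, $9,000, 14 quality-adjusted days), stage-lumped
treatment costs at diagnosis (early $55,000, late $160,000) plus a terminal
care cost ($75,000) at CRC death — a stand-in for phase-based costing that
preserves the treatment-cost offset making FIT cost-saving.  Disutilities:
none for noninvasive tests (and identical for blood and stool, so no
differential), 1 day per colonoscopy, a 0.20-QALY lumped decrement per CRC
diagnosis.  All monetary values are interpreted as 2021 USD.

## Cost-effectiveness engine

All costs and benefits are discounted to age 45 at 3%/year (values exactly
at 45 undiscounted); life-years are a continuous flow integrated against the
same kernel, `(1 − (1+r)^−T)/ln(1+r)`.  Outcomes per strategy are reported
per 1000 persons for events and as per-person costs; LYG/QALYG are measured
against no screening on the same cohort.  Net monetary benefit uses
`NMB = WTP × QALYG per person − net cost per person` at WTP = $100,000/QALY.

The frontier marks strict dominance (weakly better in both QALYG and cost,
strictly in one), then removes extended-dominated strategies iteratively
(a strategy whose incremental ICER exceeds the next one's is pruned and
ICERs recomputed — equivalent to keeping the lower convex hull, verified in
tests against a brute-force convex-combination oracle).  The least effective
non-dominated strategy carries no ICER.  Exact ties keep the first strategy
in name order and are flagged.

## Threshold analysis

`ScenarioSpec` defaults reproduce the factorial design: CRC sensitivity
{74, 83, 92%} × AA sensitivity {10…50%} × interval {1, 2, 3 y} × cost
{$25…$500 by $25} = 900 scenarios at fixed 90% specificity.  Each scenario
is run on the shared cohort and classified against {no screening, annual
FIT, decennial colonoscopy}: *effectiveness-noninferior* iff its QALYG ≥ the
comparator's; *cost-effective* iff not dominated and ICER < $150,000/QALY.
Because costs do not touch health outcomes under keyed draws, scenarios
differing only in unit cost share identical QALYG — classification is
exactly monotone in cost.

Scale: analysis drivers use 5,000 persons per scenario (shared across all
900) and the acceptance-level checks 20,000; common random numbers make the
between-scenario contrasts the analysis ranks on far more stable than the
absolute levels.  A `models k` option replays the grid under k perturbed
natural-history parameter sets to mimic cross-model ranges.

## Scenario discovery

A seeded random forest (500 trees; interval and parameter-set one-hot
encoded) is trained on the binary cost-effectiveness label over the five
factors, and factors are ranked by mean decrease in Gini impurity.  Gini
importance inherently favours variables with more distinct split points
(cost has 20 levels); the package's null-stability test therefore uses a
cardinality-balanced design.  Under the shipped calibration the ranking is
dominated by cost and AA sensitivity, with CRC sensitivity last — improved
cancer sensitivity adds little once the precursor-lesion channel is open.

The top-3 factors feed a locally weighted regression (tricube weights,
degree 1, span 0.5 by default) of NMB, conditioned on 92% CRC sensitivity
and averaged over parameter-set replicates, evaluated on an evenly spaced
grid of ~10,000 points.  Interval is discrete, so the 3-D grid is realized
as one 2-D (cost × AA sensitivity) panel per interval with the point budget
split evenly (58 × 58 × 3 = 10,092 when 10,000 is requested; a warning notes
the rounding).  Degree-1 local regression reproduces a linear response
exactly, which the tests exploit as an oracle.  Contours are extracted per
panel by marching squares; the decennial-colonoscopy NMB level partitions
each panel into regions where a blood test would or would not match the
incumbent's value.  Smoothing is descriptive; no uncertainty bands are
attached.

## Numerical and design choices

* Event ages are continuous; exam ages are quantized to 1/512-year ticks
  only inside RNG keys.
* Clinical diagnosis at exactly a scheduled exam age preempts the exam
  (symptomatic diagnosis first); screening a person in the clinical state is
  a logic error by construction.
* Degenerate inputs are supported where they define useful limits: zero
  onset rate (no disease), zero-variance dwell times, a point-mass sojourn
  of zero (`meanlog = −inf`), zero discount rate.
* Overlay draws are keyed by event, not by scenario, trading a little
  cross-scenario independence for pathwise-paired contrasts; this is a
  deliberate choice and the monotonicity tests depend on it.
* Money is reported to the cent and per-1000 outcomes to one decimal in the
  CSV writers; all CSVs carry a `# seed=… config=…` provenance header.

## What the synthetic model does and does not show

The generator emulates heterogeneous risk, a precursor-mediated cancer
pathway with a multi-year detectable window, stage-dependent survival and
competing mortality — enough for screening's two mechanisms (precursor
removal and stage shift) to operate and trade off against costs.  It is
**not** calibrated to registry incidence curves by age, birth-cohort trends,
lesion location, or model-specific dwell-time posteriors, and carries a
single parameter set rather than three independent model structures.
Passing tests therefore demonstrate internal correctness and the qualitative
orderings of the analysis (which strategies dominate, how value moves with
accuracy, interval and price) at the calibrated mortality anchor — not
quantitative agreement of every outcome column with any published model
range.  Where printed ranges exist, single-point results land inside or near
them (e.g. unscreened deaths 33–35/1000, FIT QALYG ≈ 145/1000 vs 125–163,
colonoscopy QALYG ≈ 165/1000 vs 132–177); colonoscopy's CRC-death reduction
runs optimistic because the stand-in lacks post-polypectomy incident risk
beyond newly arising adenomas.

## Known limitations

Perfect adherence only; no probabilistic sensitivity analysis; no
complication mortality; single primary cancer; two-stage staging by default;
supplementary-level cost/disutility schedules are configurable placeholders
rather than published inputs.
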