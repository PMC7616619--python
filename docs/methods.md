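# Methods

## The estimand

For each drug *d* and index month *m* (index date *t* = last day of
*m*), the indicator is the proportion of the on-drug, eligible
population with *missed monitoring*: at least one test required for *d*
(FBC/LFT/U&E for all three drugs; additionally BP for leflunomide)
absent from the record in the closed window [first day of *m*−2, *t*].
Weight checks are excluded from the leflunomide requirement: they are
not consistently listed as a requirement, and they are taken at the same
appointment as BP, so BP stands in for physical checks generally.

Months are the unit of reporting and the 3-month rolling behaviour is
inherent in the window, not a post-hoc smoothing. The on-drug rule (an
issue in each of the two preceding 3-month windows) encodes established
repeat prescribing; the search windows are 3 months because the large
majority of repeat prescriptions in English general practice cover
3 months or less.

Calendar-month arithmetic is used throughout, with the day clamped to
month end (31 May − 3 months = 28/29 Feb). Whether the original
measurement used day-based (91/182-day) or calendar-month windows is not
determinable from the published description; calendar months were chosen
because the published window examples are phrased as calendar months
("1 March 2020 to 31 May 2020") and the choice is reproducible across
tools. The index date for a named month is that month's last day, which
makes the lookback exactly the named month plus the two preceding ones.

## Disclosure-control rounding

Numerator and denominator are independently rounded to the nearest 5
*before* division, at every reported granularity (population, drug,
test, subgroup, practice), and percentages are reported to one decimal
place, half-up. No ties occur when rounding integers to multiples of 5.
Consequences worth knowing:

* a rounded numerator can exceed a rounded denominator by at most one
  rounding step; raw counts never invert;
* the percentage error introduced by rounding is bounded by
  100·(2.5/D + 2.5·N/D²) for raw counts N/D, negligible at population
  scale and a few points at practice scale;
* whether subgroup counts are rounded before or after summation to the
  population level is not specified by the source description; this
  package rounds separately at each reported granularity.

Cohort-summary percentages use the sum of the rounded category counts as
the base, so each group's percentages total ~100% despite rounding.

## The synthetic EHR generator

The generator emulates the structure the measures rely on; it is a
study-design tool, not a disease model.

* **Population.** Demographics are drawn independently per patient from
  categorical distributions; the defaults are normalised from the
  published composition of the national DMARD cohort (counts rounded to
  5), e.g. 60.9% female, 91.1% White, 24.8% aged 70–79. Ethnicity and
  region include an explicit `missing` category (0.8%/0.3%); age, sex,
  IMD and rurality are complete by default because such patients would
  be excluded, with `missing_core_fraction` available to exercise the
  exclusion rule. Practices are assigned uniformly. Registration
  predates the study (no churn is modelled; the measurement rule only
  uses a start date). Deaths occur at a small constant hazard
  (1%/year).
* **Prescribing.** Each patient draws one primary drug from
  `drug_prevalence` (defaults 63% methotrexate / 25% azathioprine / 6%
  leflunomide, the published per-drug denominator shares scaled to a 94%
  on-drug fraction); with probability `combination_therapy_rate`
  (default 2%) a second, different drug is added. A categorical primary
  draw is used instead of independent per-drug coin flips because
  independent draws at these prevalences would put >20% of patients on
  multiple drugs, whose shared blood panels would cover every drug's
  requirement at once and pull the measured miss rate far below the
  configured per-window miss probability — multi-drug patients exist
  but as a small minority, as in practice. Issues start at a uniformly
  staggered offset within the first interval after the study start and
  repeat at jittered intervals (84 ± 7 days, jitter truncated at ±6 SD
  and gaps floored at 1 day), ending at discontinuation (geometric with
  per-interval hazard, default 1%), death or study end.
* **Monitoring.** Due windows are anchored at the first prescription of
  each patient–drug pair and repeat every 91 days — 13 weeks, decoupled
  from the 84-day prescribing interval so that calendar alignment is not
  artificial. At each due date the patient attends with probability
  1 − π, where logit(π) = β₀ + practice effect + subgroup offsets +
  patient frailty + shock(t). On attendance one event per required
  blood test is recorded on that date (panels are drawn together); the
  BP check for leflunomide gets an independent draw with an extra
  offset (default +0.8 logits), making BP the most-missed test, as
  observed in national data. The shock equals `lockdown_shock_logit`
  between 23 March and 30 June 2020 and decays linearly on the logit
  scale to zero by 30 September 2020 — the simplest shape producing an
  acute rise with rapid recovery.
* **Defaults for the miss level.** β₀ = logit(0.28) and shock =
  logit(0.41) − logit(0.28), i.e. baseline and fully-shocked per-window
  miss probabilities of 0.28 and 0.41, the pre/post-disruption levels
  the analysis is designed around. Practice intercepts default to
  SD 0.8 logits, giving a realistic interdecile spread of
  practice-level rates; subgroup offsets default to a qualitative
  pattern (younger, more deprived, urban, SMI/learning-disability
  patients miss more; care-home/dementia/housebound status roughly
  neutral). Patient frailty defaults to 0 (no published value exists to
  match for within-patient correlation beyond the events-per-unique-
  patient ratio); it can be switched on via `patient_frailty_sd`.
* **Randomness.** All draws flow from `seed` through three independent
  sub-streams (population, prescribing, tests), so varying only the
  miss-mechanism parameters keeps the cohort and prescribing fixed —
  common random numbers, which make the shock-monotonicity property
  exactly testable.

### What the generator does *not* emulate

No SNOMED/dm+d coding, no incident (mid-study) therapy starts, no
registration churn, no secondary-care events or prescriptions, no
COVID-19 infection dynamics, no correlation between demographics and
practice, and no drug-specific miss levels beyond the BP mechanism.
Passing tests therefore demonstrate that the measurement and inference
machinery is correct and well-calibrated under the stated data-
generating process — not that real-world rates equal the simulated
ones. Published national magnitudes (e.g. a practice median of 25% at
baseline, regional Q ≈ 79) depend on confidential records and are out of
reach at desk scale by design.

## Known measurement artefacts

* **Ramp-in.** The study window opens 2019-09-01, but the on-drug rule
  looks back 6 months, so denominators for November 2019–January 2020
  are truncated and fill up by February 2020. The named analysis months
  (February 2020 baseline, May 2020 lockdown window, July 2022
  recovery) are unaffected.
* **Window-length sawtooth.** Monthly lookbacks span 89–92 days while
  due windows repeat every 91; months with short lookbacks have a
  slightly elevated measured rate (a patient can be covered just outside
  the window). February and June — the months used for parameter
  recovery — both have 91-day lookbacks and are unbiased.
* **Stale denominators.** A patient who discontinues remains on-drug
  for up to ~3 months afterwards while monitoring has stopped, slightly
  inflating measured rates when the discontinuation hazard is large.

## Inference

* **Change test.** The period-change test is implemented as a pooled
  two-proportion z-test on the rounded aggregate counts, with a Wald
  95% interval on the percentage-point difference. The source
  description says only "t-tests"; the compared quantities are aggregate
  proportions, so the z-on-aggregates reading was adopted and is the
  default. A Welch two-sample t-test on practice-level rates is exposed
  (`practice_change_test`) as the alternative reading but is not used in
  reports.
* **Cochran's Q.** Standard fixed-effect heterogeneity statistic with
  inverse-variance weights, computed on the proportion scale (changes
  and variances must share a scale; mixing percentage-point changes with
  proportion-scale variances would inflate Q by 10⁴). Proportions are
  clamped to [0.5/n, 1 − 0.5/n] before variance computation so
  degenerate categories keep positive variance. Q scales linearly under
  a uniform rescaling of all weights (only the weighted mean is
  invariant); the Monte-Carlo calibration confirms the χ²(k−1) null at
  the denominators used here.
* **Deciles.** d1…d9 by linear interpolation between order statistics
  (the default of mainstream statistical environments); at least two
  practice rates are required, and practices with a zero rounded
  denominator are excluded.

## Problem sizes used by the checks

The test suite and acceptance script use 5000-patient simulations for
parameter recovery (binomial SE ≈ 0.64 pp at π = 0.28, so both levels
are recovered within ≈ 2 pp), 50 randomized micro-cohorts of 40–200
patients for brute-force equivalence, and 2000 Monte-Carlo replicates
(k = 9, n = 2000 per category) for Q calibration. These sizes give
stable checks while keeping a full run in seconds; the generator scales
linearly if larger cohorts are wanted.

## Degenerate inputs and numerical choices

Zero denominators yield NaN percentages (an undefined-result signal,
not an error); an empty dataset yields empty denominators; unknown drug
or test labels, empty drug sets and per-test scopes with no qualifying
drug raise configuration errors; malformed patient dates raise data
errors naming the record. Percentages and percentage-point changes are
rounded half-up via decimal arithmetic to avoid float-representation
surprises at the 1-decimal boundary.
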