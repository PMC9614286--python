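# Methods

`iadprev` reconstructs androgen-deprivation treatment histories from
pharmacy dispensation claims and estimates how often prostate-cancer
patients follow an *intermittent* rather than continuous regimen. This
note documents the model, its tunables, the synthetic registry used for
validation, and the numerical conventions.

## Exposure model

Depot LHRH-analogue injections confer a nominal duration of action that
depends on drug and dose (one day for daily formulations; 1, 2, 3, 6 or
12 months for depots). For each patient we:

1. sort the LHRH dispensations by date, merging same-day rows of the
   same formulation with units summed (registry extracts often split one
   visit across rows);
2. form the **interval times** between consecutive dispensation dates;
3. track the **effect of the last dose** (ELD): each dispensation at
   date *d* with per-unit duration *e* and *u* units covers the
   half-open window [*d*, *d* + *e·u*). With carry-forward (default),
   the running coverage end is `max(previous end, d + e·u)`, so an early
   refill never forfeits unexpired coverage — uncovered days in an
   interval are `max(0, next_date − coverage_end)`;
4. declare an **off period** (potentially intermittent interval time)
   for every interval whose uncovered stretch reaches the minimum gap,
   anchored at the coverage-end date and terminating at the next
   dispensation. The open-ended stretch after the final dispensation is
   never an off period: a stop without an observed restart (death,
   progression, true discontinuation) is not intermittency.

The carry-forward arithmetic is provably equivalent to taking maximal
uncovered runs in the union of dose windows; the package carries an
independent per-day brute-force oracle (`day_grid_oracle`) and the test
suite asserts exact agreement on thousands of fuzzed histories. A
`carry_forward=False` mode (each interval judged from its opening dose
only) is available for sensitivity analysis.

**Minimum gap.** Default 91 days (three nominal months). Clinical
intermittency pauses typically begin only after ~6 months of continuous
treatment with confirmed castration, so a three-month floor is a
deliberately conservative detector: it can only overcount intermittency
relative to a six-month rule, and detected counts are monotonically
non-increasing in the threshold (tested).

**Calendar policy.** Months convert to days at 30.44 d/month
(365.25/12) with nearest-day rounding: 1 m→30 d, 2 m→61 d, 3 m→91 d,
6 m→183 d, 12 m→365 d. Daily formulations are stored as 1/30.44 months
so one unit covers exactly one day under any policy in [28, 31].

## Cohort rules

Included: men ≥ 18 years at first dispensation with ≥ 1 LHRH
dispensation. Excluded, with full accounting in an exclusion log:
under-18 patients (likely precocious-puberty indications),
antiandrogen-only patients (castration not guaranteed), and explicitly
configured (region, year) strata with unreliable data. Stratum
exclusion is never automatic — `qc_region_years` flags region-years
below half the region's median annual count (requiring ≥ 3 observed
years) as an advisory report. Patients whose entire LHRH evidence falls
in a dropped stratum are removed and counted; this makes the filter
idempotent. Antiandrogen rows of retained patients are kept for
combination and cost accounting but never contribute coverage.

## Estimators

* **Annual P_IAD** — patients with ≥ 1 off-period day overlapping a
  calendar year, divided by patients with ≥ 1 day of LHRH coverage in
  that year (half-open day accounting at year boundaries). Wilson score
  95% intervals; the Wilson form is used because prevalences sit near
  zero, where Wald intervals degenerate. The first window year is
  refused by default (`FirstYearExcluded`): pauses already open at the
  window start cannot be recognised, so its estimate is biased low; an
  explicit override computes it anyway and pipeline output flags it.
* **Mean annual P_IAD** — unweighted arithmetic mean of the annual
  values (strata with defined prevalence only). This reproduces the
  published headline when fed published annual values, so unweighted
  averaging is the default.
* **Global (ever-intermittent) share** — patients with any off period
  over all included patients. Pooling years overstates any single
  year's prevalence (different patients pause in different years), so
  this is reported as context, not as the headline.
* **%IAD** — total off-period days over total days between first and
  last dispensation. Denominator defaults to *all* included patients
  (the published near-equality of %IAD and mean annual P_IAD is only
  arithmetically plausible with that scope); an IAD-patients-only scope
  is available.
* **Off-period summaries** — median, IQR (Q3−Q1), min, max in months,
  with linear-interpolation quantiles (numpy default): a stated
  convention beats an unstated one.
* **Chi-square** — Pearson test of independence without continuity
  correction (large-sample registry setting); `scipy` backend, validated
  against the 2×2 closed form.

Costs are attributed to the dispense-date year, summed per (year,
region, drug, drug class) and normalised as euros per dispensation;
SD is the sample SD (n−1). The per-dispensation mean pools LHRH and
antiandrogen rows by default, with a class filter.

## Synthetic registry

The generator emulates a four-region Spanish dispensation extract over
2011–2016 and is the package's validation instrument. Defaults:

| parameter | default | rationale |
|---|---|---|
| age at first dispensation | N(76.9, 10.4²) truncated [40, 100] y | elderly ADT population |
| region mix | 0.512 / 0.330 / 0.108 / 0.050 | patient shares of the four communities |
| drug mix (per patient) | leuprorelin .5172, triptorelin .3472, goserelin .1233, rest buserelin/histrelin | dominant-agonist shares |
| intermittent fraction | 0.17 | pooled ever-intermittent share |
| off-period law | lognormal(ln 5.3, 0.6), truncated 3–58 months | truncated median ≈ 6 months |
| refill jitter | N(0, 7 d) clipped ±28 d | realistic refill slack, never gap-forming |
| cost | N(214, 32) € per dispensation, ≥ 0 | aggregate cost level; no per-drug price table |
| combination therapy | p=0.3 per on-treatment month (bicalutamide) | frequent co-dispensation |
| contamination | 0.5% under-18, 11.7% antiandrogen-only | exercises the exclusion rules |

Each patient's depot schedule follows the drug-specific duration with
jitter; intermittent patients insert 1–2 pauses after ≥ 2 on-treatment
doses, always restarting inside the window. Re-initiation jitter is
non-negative, so a realised pause never falls below the 91-day
detection floor — ground truth is detectable *by construction*, and the
parameter-recovery tests assert that the detected intermittent-patient
set equals the generating truth exactly, with cohort counts inside
exact-binomial envelopes of the configured rate.

What the generator does **not** emulate: drug switching within a
patient, multi-unit dispensations (default 1 unit; multi-unit behaviour
is exercised by explicit fixtures), dose titration, prescriber
structure, mortality/censoring mid-window, per-drug price differences,
and secular price trends. Passing recovery tests therefore demonstrate
the correctness of the episode arithmetic and estimators under the
stated exposure model — not robustness to data pathologies absent from
the simulation (e.g. misclassified ATC codes or truncated histories at
the window edges, beyond the first-year effect handled explicitly).

## Numerical and degenerate-input conventions

Dates are exact calendar days; no fractional-day arithmetic. Dose
matching uses a 1e-6 mg tolerance; the "≤ 2 mg" daily band matches any
positive dose up to 2 mg. Single-dispensation patients have zero span
and no intervals; %IAD with a zero-day denominator, prevalence with an
empty denominator, and first-year requests raise typed errors rather
than returning NaN. Empty strata warn (`EmptyStratumWarning`) and
return empty/NaN results. All randomness flows from a single
`numpy.random.default_rng(seed)`; identical config+seed is byte-identical
on disk.

## Problem sizes

The test suite validates the oracle equivalence on 1,000 fuzzed
histories, distributional conformity on a 5,000-patient cohort, and
parameter recovery on twenty 1,000-patient cohorts (four intermittency
rates × five seeds). The acceptance script runs a 3,000-patient
registry (~75k records), ample for stable headline estimates at
sub-percent Monte-Carlo error.

## Known limitations

Off periods are defined purely by LHRH coverage: antiandrogen
monotherapy during an LHRH gap does not disqualify the gap (a
documented modelling choice, flagged for sensitivity analysis).
Population-denominator treatment prevalence (per male inhabitants)
requires user-supplied census counts and is out of scope. Reproducing
the published cohort numbers exactly requires the access-controlled
registry deposit; `iadprev.deposit` implements that benchmark for users
who hold the data.
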