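# iadprev

Treatment-episode reconstruction and intermittency prevalence
estimation for androgen-deprivation therapy (ADT), from pharmacy
drug-dispensation records.

Prostate-cancer patients on ADT receive depot LHRH-analogue injections
whose effect lasts a drug/dose-specific time (1, 2, 3, 6 or 12 months).
Some patients follow an *intermittent* regimen (IAD) — deliberate
off-treatment pauses that reduce adverse effects and cost with
comparable survival — rather than *continuous* therapy (CAD). Registry
dispensation data never labels the regimen, so it must be inferred:
this package reconstructs per-patient coverage from dispensation dates
and the formulary's durations of action, detects off-treatment periods,
and estimates how prevalent intermittency is. It is written for
pharmacoepidemiologists analysing claims extracts and for
methodologists validating gap-based persistence algorithms.

## Model

For each patient, consecutive LHRH dispensations define interval times
(IntT). A dispensation at date *d* with per-unit duration of action
*e* and *u* units covers [*d*, *d* + *e·u*); unexpired coverage carries
forward across early refills (stockpiling), so the coverage end after
dose *i* is `max(end_{i-1}, d_i + e_i·u_i)`. An uncovered stretch of at
least 91 days (three months, a conservative floor) that ends at an
observed re-initiation is a *potentially intermittent interval time*
(PIIT), i.e. an off period; a trailing gap with no restart never is.

Two estimators summarise a cohort:

* **P_IAD** (annual prevalence of intermittency) = patients with ≥ 1
  off-period day in a year ÷ patients with ≥ 1 day of LHRH coverage in
  that year, with Wilson 95% intervals; the first window year is
  excluded by default because pauses already open at the window start
  are invisible;
* **%IAD** (time off treatment) = Σ off-period days ÷ Σ days between
  first and last dispensation over all included patients.

A seeded synthetic-registry generator with per-patient ground truth
(regimen and realised pauses) backs parameter-recovery tests; a
brute-force per-day coverage oracle independently validates the
interval arithmetic.

## Worked example

```python
from iadprev import (SimulationConfig, generate_cohort, apply_exclusions,
                     build_episodes, Formulary, global_p_iad,
                     mean_annual_p_iad, percent_iad, offperiod_summary)

cfg = SimulationConfig(n_patients=1000, seed=7)   # 2011-2016 window defaults
records, truth = generate_cohort(cfg)
formulary = Formulary.load()
filtered, log = apply_exclusions(records, formulary)
print(log.to_text())
episodes = build_episodes(filtered, formulary)
print("ever-intermittent share: %.1f%%" % (100 * global_p_iad(episodes).p_iad))
print("mean annual P_IAD 2012-2016: %.1f%%"
      % (100 * mean_annual_p_iad(episodes, range(2012, 2017), first_year=2011)))
print("%%IAD: %.1f%%" % (100 * percent_iad(episodes).percent_iad))
s = offperiod_summary(episodes)
print("off periods: n=%d, median %.1f months (IQR %.1f)"
      % (s.n_off_periods, s.median_months, s.iqr_months))
```

prints

```
input records:              22619
input patients:             1000
excluded, under 18:         11
excluded, antiandrogen-only:  112
patients lost to stratum exclusions: 0
final patients:             877
final records:              21038
ever-intermittent share: 18.8%
mean annual P_IAD 2012-2016: 9.8%
%IAD: 5.4%
off periods: n=215, median 5.8 months (IQR 4.5)
```

Reading: of 1,000 simulated patients, 877 survive the study's exclusion
rules (adult men with ≥ 1 LHRH dispensation). 18.8% ever pause
treatment over the six-year window — close to the generator's
configured 17% intermittent fraction — while any *single* year shows a
lower prevalence (mean 9.8%), because different patients pause in
different years. Pauses have a median near six months, and 5.4% of all
observed treatment time is spent off treatment.

The same workflow from a shell:

```
iadprev simulate --n-patients 1000 --seed 7 --out sim/
iadprev run --records sim/records.csv --out results/
iadprev report --out results/
```

`run` writes the exclusion log, per-patient episode and off-period
tables, prevalence tables with confidence intervals, %IAD and
off-period summaries, and cost tables (totals and euros per
dispensation by year/region/drug); `report` renders cost, age and
prevalence-trend charts. Region-years with unreliable data can be
dropped with `--exclude-region-year "Basque Country:2012"`.

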