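"""Treatment-episode reconstruction from LHRH-analogue dispensations.

The intermittency estimator rests on three per-patient constructs:

* **interval times** — the periods between consecutive dispensation
  dates;
* **effect of the last dose** — the coverage conferred by each depot
  injection (nominal duration of action × units dispensed), with
  unexpired coverage carried forward across early refills
  (stockpiling);
* **potentially intermittent interval times (off periods)** — maximal
  uncovered stretches of at least ``min_gap_days`` that end at an
  observed re-initiation.  The default threshold is 91 days (three
  months), a deliberately conservative floor: clinical intermittency
  pauses typically start only after around six months of continuous
  treatment, so requiring three uncovered months avoids counting
  routine refill slack as intermittency.

The open-ended period after a patient's final dispensation is never an
off period: a stop without an observed restart (death, progression to
castration resistance, true discontinuation) is not intermittency.

:func:`day_grid_oracle` provides an independent brute-force coverage
computation on a per-day grid; it exists for testing the interval
arithmetic and is never used by the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .formulary import LHRH_ANALOGUE, DurationPolicy, Formulary, classify_drug
from .records import DispensationRecord


@dataclass(frozen=True)
class EngineConfig:
    """Tunables of the episode reconstruction.

    min_gap_days:
        Minimum uncovered stretch that counts as a potential
        intermittency gap.  Default 91 days = three nominal months.
    carry_forward:
        Whether unexpired coverage from an early refill extends the next
        dose's coverage window (stockpiling).  Default on; switching it
        off makes every interval's coverage start afresh at its opening
        dispensation, a stricter convention useful for sensitivity
        analysis.
    """

    min_gap_days: int = 91
    carry_forward: bool = True
    policy: DurationPolicy = field(default_factory=DurationPolicy)

    def __post_init__(self):
        if self.min_gap_days < 1:
            raise ValueError("min_gap_days must be >= 1")


@dataclass(frozen=True)
class IntervalTime:
    """Period between two consecutive (distinct) dispensation dates."""

    patient_id: str
    start_date: date
    end_date: date
    length_days: int
    eld_days: int
    uncovered_days: int


@dataclass(frozen=True)
class OffPeriod:
    """Confirmed off-treatment period: coverage end to re-initiation."""

    patient_id: str
    start_date: date
    end_date: date
    duration_days: int


@dataclass
class PatientEpisodes:
    """Per-patient reconstruction: dispensations, intervals, off periods.

    ``coverage`` holds the merged half-open coverage segments
    ``[start, end)`` — the union of all dose windows under carry-forward
    arithmetic — used downstream for treated-in-year membership.
    """

    patient_id: str
    birth_date: date
    region: str
    dispensations: list[tuple[date, int]]  # (date, eld_days) after same-day merge
    intervals: list[IntervalTime]
    off_periods: list[OffPeriod]
    first_date: date
    last_date: date
    span_days: int
    coverage: list[tuple[date, date]]

    @property
    def total_off_days(self) -> int:
        return sum(p.duration_days for p in self.off_periods)

    @property
    def is_intermittent(self) -> bool:
        return bool(self.off_periods)


def _merged_daily_eld(
    records: list[DispensationRecord],
    formulary: Formulary,
    policy: DurationPolicy,
) -> list[tuple[date, int]]:
    """Collapse a patient's LHRH rows to one (date, eld_days) per date.

    Same-day rows of the same (drug, dose) are merged with units summed
    — registry extracts commonly split one visit across rows.  Distinct
    formulations dispensed the same day each contribute their own
    window; the day's effective coverage is the longest of them.
    """
    by_date: dict[date, dict[tuple[str, float], int]] = {}
    for r in records:
        formulary.lookup_entry(r.drug_name, r.dose_mg)  # raises UnknownDose early
        key = (r.drug_name, r.dose_mg)
        by_date.setdefault(r.dispense_date, {})
        by_date[r.dispense_date][key] = by_date[r.dispense_date].get(key, 0) + r.n_units
    out = []
    for d in sorted(by_date):
        eld = max(
            formulary.duration_days(drug, dose, policy) * units
            for (drug, dose), units in by_date[d].items()
        )
        out.append((d, eld))
    return out


def build_intervals(
    records: list[DispensationRecord],
    formulary: Formulary,
    config: EngineConfig | None = None,
) -> PatientEpisodes:
    """Reconstruct interval times and coverage for one patient.

    ``records`` are that patient's LHRH dispensations (antiandrogen rows
    are ignored if present); off periods are left empty — apply
    :func:`detect_piit` next.
    """
    config = config or EngineConfig()
    lhrh = [r for r in records if classify_drug(r.atc_code) == LHRH_ANALOGUE]
    if not lhrh:
        raise ValueError("patient has no LHRH dispensations")
    pid = lhrh[0].patient_id
    doses = _merged_daily_eld(lhrh, formulary, config.policy)

    intervals: list[IntervalTime] = []
    coverage: list[tuple[date, date]] = []
    cov_end = doses[0][0]  # running coverage end (exclusive)
    for i, (d, eld) in enumerate(doses):
        this_end = d + timedelta(days=eld)
        if config.carry_forward:
            new_end = max(cov_end, this_end)
        else:
            new_end = this_end
        # maintain merged coverage union
        if coverage and d <= coverage[-1][1]:
            coverage[-1] = (coverage[-1][0], max(coverage[-1][1], this_end))
        else:
            coverage.append((d, this_end))
        cov_end = new_end
        if i + 1 < len(doses):
            nxt = doses[i + 1][0]
            length = (nxt - d).days
            uncovered = max(0, (nxt - cov_end).days)
            intervals.append(
                IntervalTime(
                    patient_id=pid,
                    start_date=d,
                    end_date=nxt,
                    length_days=length,
                    eld_days=eld,
                    uncovered_days=min(uncovered, length),
                )
            )

    first, last = doses[0][0], doses[-1][0]
    return PatientEpisodes(
        patient_id=pid,
        birth_date=lhrh[0].birth_date,
        region=lhrh[0].region,
        dispensations=doses,
        intervals=intervals,
        off_periods=[],
        first_date=first,
        last_date=last,
        span_days=(last - first).days,
        coverage=coverage,
    )


def detect_piit(episodes: PatientEpisodes, config: EngineConfig | None = None) -> PatientEpisodes:
    """Populate off periods: uncovered interval stretches >= min_gap_days.

    Each qualifying interval yields one off period anchored at its
    coverage-end date and terminating at the next dispensation (the
    observed re-initiation).  The trailing gap after the final
    dispensation never qualifies by construction, since intervals only
    exist between consecutive dispensations.
    """
    config = config or EngineConfig()
    offs = []
    for iv in episodes.intervals:
        if iv.uncovered_days >= config.min_gap_days:
            start = iv.end_date - timedelta(days=iv.uncovered_days)
            offs.append(
                OffPeriod(
                    patient_id=episodes.patient_id,
                    start_date=start,
                    end_date=iv.end_date,
                    duration_days=iv.uncovered_days,
                )
            )
    episodes.off_periods = sorted(offs, key=lambda p: p.start_date)
    return episodes


def build_episodes(
    records: list[DispensationRecord],
    formulary: Formulary,
    config: EngineConfig | None = None,
) -> dict[str, PatientEpisodes]:
    """Run the full reconstruction for every patient in a record set.

    Patients with only antiandrogen rows are skipped (they have no LHRH
    coverage to reconstruct; upstream filtering normally removes them).
    """
    config = config or EngineConfig()
    by_patient: dict[str, list[DispensationRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    out = {}
    for pid in sorted(by_patient):
        recs = by_patient[pid]
        if not any(classify_drug(r.atc_code) == LHRH_ANALOGUE for r in recs):
            continue
        out[pid] = detect_piit(build_intervals(recs, formulary, config), config)
    return out


def day_grid_oracle(
    records: list[DispensationRecord],
    formulary: Formulary,
    window: tuple[date, date],
    policy: DurationPolicy | None = None,
) -> np.ndarray:
    """Brute-force per-day coverage indicator over ``window`` (inclusive).

    Day ``t`` is covered iff it lies in the union of the half-open
    windows ``[dispense_date, dispense_date + eld)`` after same-day
    merging.  Test oracle only — O(days × doses).
    """
    policy = policy or DurationPolicy()
    start, end = window
    n = (end - start).days + 1
    covered = np.zeros(n, dtype=bool)
    lhrh = [r for r in records if classify_drug(r.atc_code) == LHRH_ANALOGUE]
    for d, eld in _merged_daily_eld(lhrh, formulary, policy):
        lo = (d - start).days
        hi = lo + eld
        if hi <= 0 or lo >= n:
            continue
        covered[max(lo, 0) : min(hi, n)] = True
    return covered


def oracle_off_periods(
    records: list[DispensationRecord],
    formulary: Formulary,
    min_gap_days: int,
    policy: DurationPolicy | None = None,
) -> list[tuple[date, date]]:
    """Off periods via the day grid: maximal uncovered runs >= min_gap
    strictly between the first and last dispensation dates."""
    policy = policy or DurationPolicy()
    lhrh = [r for r in records if classify_drug(r.atc_code) == LHRH_ANALOGUE]
    dates = sorted(r.dispense_date for r in lhrh)
    first, last = dates[0], dates[-1]
    if first == last:
        return []
    grid = day_grid_oracle(records, formulary, (first, last), policy)
    # restrict to days strictly inside [first, last): index 0 .. span-1
    span = (last - first).days
    runs = []
    i = 0
    while i < span:
        if not grid[i]:
            j = i
            while j < span and not grid[j]:
                j += 1
            if j - i >= min_gap_days:
                runs.append((first + timedelta(days=i), first + timedelta(days=j)))
            i = j
        else:
            i += 1
    return runs
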