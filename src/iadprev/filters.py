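"""Cohort inclusion/exclusion rules and the auditable exclusion log.

The study population is adult men with at least one LHRH-analogue
dispensation.  Three exclusion rules apply, in order:

(a) patients younger than 18 years at their first dispensation — LHRH
    use in minors reflects precocious-puberty treatment, not prostate
    cancer;
(b) patients dispensed only antiandrogens — oral monotherapy does not
    guarantee castration, so intermittency cannot be defined for them;
(c) all records falling in explicitly configured (region, year) strata
    judged unreliable (e.g. an incomplete first year of an electronic
    dispensing system); patients left without any LHRH record
    afterwards are dropped and counted.

Rule (c) is configuration-driven, never automatic:
:func:`qc_region_years` reports suspect strata (a region-year whose
record count falls below half that region's median annual count) for a
human to confirm.

Antiandrogen rows of *retained* patients are kept — they feed
combination counts and cost accounting — but never contribute to
coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import UnclassifiedDrug
from .formulary import LHRH_ANALOGUE, Formulary, classify_drug
from .records import DispensationRecord


@dataclass
class ExclusionLog:
    """Patient-flow accounting: every input patient lands in exactly one bin."""

    n_input_records: int = 0
    n_input_patients: int = 0
    excluded_under18: int = 0
    excluded_antiandrogen_only: int = 0
    excluded_region_years: list[tuple[str, int, int]] = field(default_factory=list)
    n_patients_lost_region_years: int = 0
    n_final_patients: int = 0
    n_final_records: int = 0

    def check(self) -> None:
        assert self.n_final_patients == (
            self.n_input_patients
            - self.excluded_under18
            - self.excluded_antiandrogen_only
            - self.n_patients_lost_region_years
        ), "exclusion log does not reconcile"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input_records": self.n_input_records,
            "n_input_patients": self.n_input_patients,
            "excluded_under18": self.excluded_under18,
            "excluded_antiandrogen_only": self.excluded_antiandrogen_only,
            "excluded_region_years": [
                {"region": r, "year": y, "n_records": n}
                for r, y, n in self.excluded_region_years
            ],
            "n_patients_lost_region_years": self.n_patients_lost_region_years,
            "n_final_patients": self.n_final_patients,
            "n_final_records": self.n_final_records,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    def to_text(self) -> str:
        lines = [
            f"input records:              {self.n_input_records}",
            f"input patients:             {self.n_input_patients}",
            f"excluded, under 18:         {self.excluded_under18}",
            f"excluded, antiandrogen-only:{self.excluded_antiandrogen_only:>5}",
        ]
        for r, y, n in self.excluded_region_years:
            lines.append(f"excluded stratum {r} {y}: {n} records")
        lines += [
            f"patients lost to stratum exclusions: {self.n_patients_lost_region_years}",
            f"final patients:             {self.n_final_patients}",
            f"final records:              {self.n_final_records}",
        ]
        return "\n".join(lines)


def apply_exclusions(
    records: list[DispensationRecord],
    formulary: Formulary | None = None,
    excluded_region_years: list[tuple[str, int]] = (),
    min_age_years: int = 18,
) -> tuple[list[DispensationRecord], ExclusionLog]:
    """Apply the three study exclusion rules; return kept records and the log.

    Idempotent and order-independent: shuffling the input changes
    neither the kept set nor the counts.  A record whose ATC code falls
    outside both drug families raises :class:`UnclassifiedDrug` with row
    context.
    """
    log = ExclusionLog(
        n_input_records=len(records),
        n_input_patients=len({r.patient_id for r in records}),
    )
    classes = {}
    for r in records:
        try:
            classes[id(r)] = classify_drug(r.atc_code)
        except UnclassifiedDrug:
            raise UnclassifiedDrug(
                r.atc_code,
                context=f"patient {r.patient_id}, {r.dispense_date}, drug {r.drug_name!r}",
            ) from None

    by_patient: dict[str, list[DispensationRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    dropped_strata = {(reg, int(y)) for reg, y in excluded_region_years}
    stratum_counts: dict[tuple[str, int], int] = {s: 0 for s in dropped_strata}

    kept: list[DispensationRecord] = []
    final_patients = 0
    for pid in sorted(by_patient):
        rows = sorted(by_patient[pid], key=lambda r: r.dispense_date)
        first = rows[0]
        age_at_first = (first.dispense_date - first.birth_date).days / 365.25
        if age_at_first < min_age_years:
            log.excluded_under18 += 1
            continue
        if not any(classes[id(r)] == LHRH_ANALOGUE for r in rows):
            log.excluded_antiandrogen_only += 1
            continue
        remaining = []
        for r in rows:
            stratum = (r.region, r.dispense_date.year)
            if stratum in dropped_strata:
                stratum_counts[stratum] += 1
            else:
                remaining.append(r)
        if not any(classes[id(r)] == LHRH_ANALOGUE for r in remaining):
            # all usable (LHRH) evidence for this patient fell in dropped strata
            log.n_patients_lost_region_years += 1
            continue
        kept.extend(remaining)
        final_patients += 1

    log.excluded_region_years = sorted(
        (reg, y, n) for (reg, y), n in stratum_counts.items()
    )
    log.n_final_patients = final_patients
    log.n_final_records = len(kept)
    log.check()
    # full-tuple sort so the output order never depends on input order
    kept.sort(
        key=lambda r: (r.patient_id, r.dispense_date, r.atc_code, r.drug_name,
                       r.dose_mg, r.n_units, r.cost_eur)
    )
    return kept, log


def qc_region_years(
    records: list[DispensationRecord],
    threshold: float = 0.5,
    min_years: int = 3,
) -> list[tuple[str, int, int, float]]:
    """Flag region-years with suspiciously low record counts.

    A (region, year) is flagged when its record count is below
    ``threshold`` × the region's median annual count.  Regions observed
    in fewer than ``min_years`` distinct years are never flagged (a
    median over one or two years is meaningless).  Advisory only: actual
    exclusion happens solely through configuration.

    Returns ``(region, year, record_count, region_median_count)`` tuples.
    """
    import statistics

    counts: dict[str, dict[int, int]] = {}
    for r in records:
        counts.setdefault(r.region, {}).setdefault(r.dispense_date.year, 0)
        counts[r.region][r.dispense_date.year] += 1
    flagged = []
    for region in sorted(counts):
        per_year = counts[region]
        if len(per_year) < min_years:
            continue
        med = statistics.median(per_year.values())
        for year in sorted(per_year):
            if per_year[year] < threshold * med:
                flagged.append((region, year, per_year[year], float(med)))
    return flagged
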