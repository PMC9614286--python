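"""Drug formulary: dose-specific depot durations and ATC classification.

Androgen-deprivation therapy for prostate cancer is dominated by
sustained-release ("depot") LHRH-analogue injections whose nominal
duration of action — one day to twelve months — depends on the drug and
the dose dispensed.  Reconstructing treatment coverage from pharmacy
claims therefore starts from a formulary mapping each ``(drug, dose)``
pair to its expected duration of action.  This module ships that table
for the six LHRH analogues marketed in Spain during 2011–2016
(leuprorelin, triptorelin, goserelin, buserelin, histrelin, nafarelin)
plus the oral antiandrogens (bicalutamide, flutamide), and exposes

* :func:`lookup_duration` / :meth:`Formulary.lookup_duration` — nominal
  months of coverage for a dispensation;
* :func:`classify_drug` — LHRH analogue vs antiandrogen from the ATC code;
* :func:`months_to_days` — calendar conversion under a
  :class:`DurationPolicy`.

Day-strength formulations (daily subcutaneous or intranasal forms,
listed with doses ≤ 2 mg) are stored with a fractional month duration
such that one dispensed unit covers one day under any calendar policy
between 28 and 31 days per month.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import InvalidDuration, UnclassifiedDrug, UnknownDose, UnknownDrug

LHRH_ANALOGUE = "lhrh_analogue"
ANTIANDROGEN = "antiandrogen"

#: ATC prefixes of the two drug families handled by the pipeline.
_LHRH_ATC_PREFIXES = ("L02AE", "H01CA")
_ANTIANDROGEN_ATC_PREFIXES = ("L02BB",)

#: Spelling variants (Spanish / French-style '-ine' endings) mapped to the
#: canonical international non-proprietary name.
_ALIASES = {
    "leuproreline": "leuprorelin",
    "leuprorelina": "leuprorelin",
    "leuprolide": "leuprorelin",
    "gosereline": "goserelin",
    "goserelina": "goserelin",
    "busereline": "buserelin",
    "buserelina": "buserelin",
    "triptoreline": "triptorelin",
    "triptorelina": "triptorelin",
    "histreline": "histrelin",
    "histrelina": "histrelin",
    "nafareline": "nafarelin",
    "nafarelina": "nafarelin",
    "bicalutamida": "bicalutamide",
    "flutamida": "flutamide",
}

_DOSE_TOL = 1e-6


def canonical_name(name: str) -> str:
    """Canonicalise a drug name: lowercase, strip accents, resolve aliases."""
    decomposed = unicodedata.normalize("NFKD", name.strip().lower())
    plain = "".join(c for c in decomposed if not unicodedata.combining(c))
    return _ALIASES.get(plain, plain)


@dataclass(frozen=True)
class DurationPolicy:
    """Calendar convention for converting nominal months to whole days.

    The default 30.44 days/month (365.25 / 12) gives 1 m → 30 d,
    2 m → 61 d, 3 m → 91 d, 6 m → 183 d and 12 m → 365 d with
    nearest-day rounding.
    """

    days_per_month: float = 30.44

    def __post_init__(self):
        if not 28.0 <= self.days_per_month <= 31.0:
            raise InvalidDuration(
                f"days_per_month must lie in [28, 31], got {self.days_per_month}"
            )


def months_to_days(duration_months: float, policy: DurationPolicy | None = None) -> int:
    """Convert a nominal month duration to whole days (nearest-day rounding)."""
    if duration_months < 0:
        raise InvalidDuration(f"duration must be non-negative, got {duration_months}")
    policy = policy or DurationPolicy()
    return round(duration_months * policy.days_per_month)


@dataclass(frozen=True)
class FormularyEntry:
    """One formulary row: a dose (or dose band) of one drug.

    Exact doses have ``dose_mg_low == dose_mg_high``; the daily
    formulations listed under "≤ 2 mg" are stored as the band (0, 2].
    """

    drug_name: str
    atc_code: str
    dose_mg_low: float
    dose_mg_high: float
    duration_months: float
    drug_class: str

    def matches_dose(self, dose_mg: float) -> bool:
        if self.dose_mg_low == self.dose_mg_high:
            return abs(dose_mg - self.dose_mg_low) <= _DOSE_TOL
        return self.dose_mg_low < dose_mg <= self.dose_mg_high + _DOSE_TOL


class Formulary:
    """Lookup table from (drug, dose) to duration of action and drug class."""

    def __init__(self, entries: list[FormularyEntry]):
        self.entries = list(entries)
        self._by_drug: dict[str, list[FormularyEntry]] = {}
        for e in self.entries:
            self._by_drug.setdefault(e.drug_name, []).append(e)
        seen = set()
        for e in self.entries:
            key = (e.drug_name, e.dose_mg_low, e.dose_mg_high)
            if key in seen:
                raise ValueError(f"duplicate formulary entry {key}")
            seen.add(key)
            if e.duration_months <= 0:
                raise InvalidDuration(f"non-positive duration in entry {key}")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "Formulary":
        """Load the bundled formulary, or a user-supplied CSV override.

        The CSV columns are ``drug_name, atc_code, dose_mg_low,
        dose_mg_high, duration_months, drug_class``.
        """
        if path is None:
            source = resources.files("iadprev.data").joinpath("formulary.csv")
            text = source.read_text(encoding="utf-8")
        else:
            text = Path(path).read_text(encoding="utf-8")
        entries = []
        for row in csv.DictReader(text.splitlines()):
            entries.append(
                FormularyEntry(
                    drug_name=canonical_name(row["drug_name"]),
                    atc_code=row["atc_code"].strip(),
                    dose_mg_low=float(row["dose_mg_low"]),
                    dose_mg_high=float(row["dose_mg_high"]),
                    duration_months=float(row["duration_months"]),
                    drug_class=row["drug_class"].strip(),
                )
            )
        return cls(entries)

    @property
    def drugs(self) -> list[str]:
        return sorted(self._by_drug)

    def entries_for(self, drug_name: str) -> list[FormularyEntry]:
        drug = canonical_name(drug_name)
        if drug not in self._by_drug:
            raise UnknownDrug(drug_name)
        return list(self._by_drug[drug])

    def lookup_entry(self, drug_name: str, dose_mg: float) -> FormularyEntry:
        for entry in self.entries_for(drug_name):
            if entry.matches_dose(dose_mg):
                return entry
        raise UnknownDose(canonical_name(drug_name), dose_mg)

    def lookup_duration(self, drug_name: str, dose_mg: float) -> float:
        """Nominal duration of action in months for one dispensed unit."""
        return self.lookup_entry(drug_name, dose_mg).duration_months

    def duration_days(
        self, drug_name: str, dose_mg: float, policy: DurationPolicy | None = None
    ) -> int:
        """Whole-day duration of action for one dispensed unit."""
        return months_to_days(self.lookup_duration(drug_name, dose_mg), policy)


def classify_drug(atc_code: str) -> str:
    """Classify an ATC code as ``lhrh_analogue`` or ``antiandrogen``.

    LHRH agonists sit under L02AE (endocrine therapy) and H01CA
    (hypothalamic hormones); antiandrogens under L02BB.  Any other code
    raises :class:`UnclassifiedDrug`.
    """
    code = atc_code.strip().upper()
    if not code:
        raise UnclassifiedDrug(atc_code)
    if code.startswith(_LHRH_ATC_PREFIXES):
        return LHRH_ANALOGUE
    if code.startswith(_ANTIANDROGEN_ATC_PREFIXES):
        return ANTIANDROGEN
    raise UnclassifiedDrug(atc_code)


def lookup_duration(drug_name: str, dose_mg: float) -> float:
    """Module-level convenience using the bundled formulary."""
    return _default().lookup_duration(drug_name, dose_mg)


_DEFAULT: Formulary | None = None


def _default() -> Formulary:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Formulary.load()
    return _DEFAULT
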