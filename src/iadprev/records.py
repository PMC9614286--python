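"""Dispensation-record schema and delimited-file I/O.

The canonical on-disk format is a UTF-8 CSV with header

    patient_id,birth_date,region,dispense_date,drug_name,atc_code,dose_mg,n_units,cost_eur

ISO-8601 dates and a dot decimal separator.  One row is one pharmacy
dispensation event.  Readers validate every row and report all
offending line numbers at once rather than stopping at the first.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from datetime import date, datetime
from pathlib import Path

import pandas as pd

from .errors import SchemaError

RECORD_COLUMNS = [
    "patient_id",
    "birth_date",
    "region",
    "dispense_date",
    "drug_name",
    "atc_code",
    "dose_mg",
    "n_units",
    "cost_eur",
]


@dataclass(frozen=True)
class DispensationRecord:
    """One dispensation event from a pharmacy-claims extract."""

    patient_id: str
    birth_date: date
    region: str
    dispense_date: date
    drug_name: str
    atc_code: str
    dose_mg: float
    n_units: int
    cost_eur: float

    def __post_init__(self):
        if self.dose_mg <= 0:
            raise ValueError(f"dose_mg must be positive, got {self.dose_mg}")
        if self.n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {self.n_units}")
        if self.cost_eur < 0:
            raise ValueError(f"cost_eur must be non-negative, got {self.cost_eur}")


def records_to_frame(records: list[DispensationRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [[getattr(r, f.name) for f in fields(DispensationRecord)] for r in records],
        columns=RECORD_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[DispensationRecord]:
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            DispensationRecord(
                patient_id=str(row.patient_id),
                birth_date=_as_date(row.birth_date),
                region=str(row.region),
                dispense_date=_as_date(row.dispense_date),
                drug_name=str(row.drug_name),
                atc_code=str(row.atc_code),
                dose_mg=float(row.dose_mg),
                n_units=int(row.n_units),
                cost_eur=float(row.cost_eur),
            )
        )
    return out


def _as_date(value) -> date:
    if isinstance(value, datetime):  # includes pandas Timestamp
        return value.date()
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value)[:10])


def write_records(records: list[DispensationRecord], path: str | Path) -> None:
    """Write records as the canonical CSV (lossless round-trip)."""
    records_to_frame(records).to_csv(path, index=False)


def read_records(path: str | Path) -> list[DispensationRecord]:
    """Read and validate a canonical dispensation CSV.

    Raises :class:`SchemaError` for a missing column, or with the
    1-based line numbers of every malformed row (unparseable date,
    non-positive dose, missing field...).  An empty file with a valid
    header yields an empty list.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError("file is empty (no header)") from None
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    records, bad = [], []
    for i, row in enumerate(frame.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            records.append(
                DispensationRecord(
                    patient_id=row.patient_id,
                    birth_date=date.fromisoformat(row.birth_date),
                    region=row.region,
                    dispense_date=date.fromisoformat(row.dispense_date),
                    drug_name=row.drug_name,
                    atc_code=row.atc_code,
                    dose_mg=float(row.dose_mg),
                    n_units=int(row.n_units),
                    cost_eur=float(row.cost_eur),
                )
            )
        except (ValueError, TypeError):
            bad.append(line_no)
    if bad:
        raise SchemaError("malformed rows", rows=bad)
    return records


def import_spreadsheet(
    path: str | Path,
    column_map: dict[str, str],
    sheet: int | str = 0,
) -> list[DispensationRecord]:
    """Convert a registry spreadsheet extract to canonical records.

    ``column_map`` maps canonical column names (see ``RECORD_COLUMNS``)
    to the spreadsheet's column headers; unmapped optional columns
    (``n_units`` defaulting to 1, ``cost_eur`` to 0) may be omitted.
    """
    raw = pd.read_excel(path, sheet_name=sheet)
    frame = pd.DataFrame()
    for canonical in RECORD_COLUMNS:
        if canonical in column_map:
            source = column_map[canonical]
            if source not in raw.columns:
                raise SchemaError(f"spreadsheet lacks mapped column {source!r}")
            frame[canonical] = raw[source]
        elif canonical == "n_units":
            frame[canonical] = 1
        elif canonical == "cost_eur":
            frame[canonical] = 0.0
        else:
            raise SchemaError(f"column_map lacks required column {canonical!r}")
    return frame_to_records(frame)
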