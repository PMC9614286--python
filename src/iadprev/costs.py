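"""Expenditure aggregation: totals and euros per dispensation.

Costs are attributed to the calendar year of the dispense date and
summed per requested stratum (year, region, drug, drug class).  To make
regions of very different size comparable, totals are normalised as
euros per dispensation.  Configured (region, year) strata with known
incomplete data can be excluded from all totals; they are listed on the
result for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import EmptyStratumWarning, InvalidCost
from .formulary import classify_drug
from .records import DispensationRecord, records_to_frame

GROUP_FIELDS = ("year", "region", "drug", "drug_class")


@dataclass(frozen=True)
class CostSummary:
    """Expenditure in one stratum.  Unused grouping fields hold "all"."""

    year: int | str
    region: str
    drug: str
    drug_class: str
    n_dispensations: int
    total_eur: float
    eur_per_dispensation: float


def _cost_frame(records: list[DispensationRecord]) -> pd.DataFrame:
    frame = records_to_frame(records)
    negative = frame.index[frame["cost_eur"] < 0].tolist()
    if negative:
        raise InvalidCost(f"negative cost in rows {negative}", rows=negative)
    frame["year"] = frame["dispense_date"].map(lambda d: d.year)
    frame["drug"] = frame["drug_name"]
    frame["drug_class"] = frame["atc_code"].map(classify_drug)
    return frame


def annual_costs(
    records: list[DispensationRecord],
    group_by: tuple[str, ...] = ("year", "drug_class"),
    excluded_region_years: list[tuple[str, int]] = (),
) -> tuple[list[CostSummary], list[tuple[str, int]]]:
    """Sum costs per stratum after dropping excluded (region, year) strata.

    ``group_by`` is any subset of ``{"year", "region", "drug",
    "drug_class"}``.  Returns the summaries (deterministically sorted)
    and the excluded strata that actually removed records.
    """
    unknown = set(group_by) - set(GROUP_FIELDS)
    if unknown:
        raise ValueError(f"unknown grouping fields {sorted(unknown)}")
    if not records:
        return [], []
    frame = _cost_frame(records)
    dropped = {(r, int(y)) for r, y in excluded_region_years}
    if dropped:
        mask = frame.apply(lambda row: (row["region"], row["year"]) in dropped, axis=1)
        hit = sorted(
            {(row.region, int(row.year)) for row in frame[mask].itertuples()}
        )
        frame = frame[~mask]
    else:
        hit = []
    keys = [f for f in GROUP_FIELDS if f in group_by]
    grouped = frame.groupby(keys, sort=True)["cost_eur"].agg(["sum", "count"])
    out = []
    for key, row in grouped.iterrows():
        key = key if isinstance(key, tuple) else (key,)
        stratum = dict(zip(keys, key))
        total = float(row["sum"])
        n = int(row["count"])
        out.append(
            CostSummary(
                year=stratum.get("year", "all"),
                region=stratum.get("region", "all"),
                drug=stratum.get("drug", "all"),
                drug_class=stratum.get("drug_class", "all"),
                n_dispensations=n,
                total_eur=total,
                eur_per_dispensation=total / n,
            )
        )
    return out, hit


def costs_frame(summaries: list[CostSummary]) -> pd.DataFrame:
    """Tidy table of cost summaries (one stratum per row)."""
    return pd.DataFrame(
        [
            [s.year, s.region, s.drug_class, s.drug, s.n_dispensations,
             s.total_eur, s.eur_per_dispensation]
            for s in summaries
        ],
        columns=["year", "region", "drug_class", "drug",
                 "n_dispensations", "total_eur", "eur_per_dispensation"],
    )


def mean_cost_per_dispensation(
    records: list[DispensationRecord],
    year: int,
    drug_class: str | None = None,
) -> tuple[float, float]:
    """Mean and sample SD (n−1) of per-dispensation cost in one year.

    Pools LHRH and antiandrogen rows by default; pass ``drug_class`` to
    restrict.  An empty year warns and returns NaNs.
    """
    import warnings

    import numpy as np

    costs = [
        r.cost_eur
        for r in records
        if r.dispense_date.year == year
        and (drug_class is None or classify_drug(r.atc_code) == drug_class)
    ]
    if not costs:
        warnings.warn(f"no dispensations in {year}", EmptyStratumWarning, stacklevel=2)
        return float("nan"), float("nan")
    arr = np.asarray(costs, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd
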