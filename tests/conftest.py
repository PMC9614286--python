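"""Shared fixtures: formulary, record factory, reusable synthetic cohorts."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from iadprev import Formulary, SimulationConfig, generate_cohort
from iadprev.records import DispensationRecord


@pytest.fixture(scope="session")
def formulary() -> Formulary:
    return Formulary.load()


@pytest.fixture()
def make_record():
    """Factory for dispensation records with sensible defaults."""

    def _make(
        patient_id="P1",
        birth_date=date(1940, 5, 1),
        region="Catalonia",
        dispense_date=date(2012, 3, 1),
        drug_name="goserelin",
        atc_code="L02AE03",
        dose_mg=10.8,
        n_units=1,
        cost_eur=200.0,
    ):
        return DispensationRecord(
            patient_id=patient_id,
            birth_date=birth_date,
            region=region,
            dispense_date=dispense_date,
            drug_name=drug_name,
            atc_code=atc_code,
            dose_mg=dose_mg,
            n_units=n_units,
            cost_eur=cost_eur,
        )

    return _make


@pytest.fixture()
def depot_series(make_record):
    """Series of dispensations for one patient at given day offsets."""

    def _series(day_offsets, origin=date(2012, 1, 10), **kwargs):
        return [
            make_record(dispense_date=origin + timedelta(days=int(d)), **kwargs)
            for d in day_offsets
        ]

    return _series


@pytest.fixture(scope="session")
def default_cohort():
    """Medium synthetic cohort under the default study conditions."""
    cfg = SimulationConfig(n_patients=800, seed=20260930)
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for distributional checks (n = 5000)."""
    cfg = SimulationConfig(n_patients=5000, seed=11)
    return cfg, *generate_cohort(cfg)
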