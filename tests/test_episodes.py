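"""Episode engine: interval construction, carry-forward coverage,
off-period detection, and equivalence with the day-grid oracle."""

from datetime import date, timedelta

import numpy as np
import pytest

from iadprev import EngineConfig, build_intervals, detect_piit
from iadprev.episodes import day_grid_oracle, oracle_off_periods
from iadprev.errors import UnknownDose


def _episodes(records, formulary, **cfg_kwargs):
    config = EngineConfig(**cfg_kwargs)
    return detect_piit(build_intervals(records, formulary, config), config)


def test_single_dispensation_has_no_intervals(depot_series, formulary):
    ep = build_intervals(depot_series([0]), formulary)
    assert ep.intervals == []
    assert ep.span_days == 0


def test_refill_before_expiry_leaves_no_uncovered_days(depot_series, formulary):
    # two 3-month depots (91-day coverage) 80 days apart
    ep = build_intervals(depot_series([0, 80]), formulary)
    (iv,) = ep.intervals
    assert iv.length_days == 80
    assert iv.eld_days == 91
    assert iv.uncovered_days == 0


def test_late_refill_uncovered_days_and_off_period(depot_series, formulary):
    # 200 days between 91-day depots: 109 uncovered days, above the 91-day gap
    ep = _episodes(depot_series([0, 200]), formulary)
    (iv,) = ep.intervals
    assert iv.uncovered_days == 200 - 91 == 109
    (off,) = ep.off_periods
    assert off.duration_days == 109
    assert off.start_date == iv.start_date + timedelta(days=91)
    assert off.end_date == iv.end_date


def test_overlapping_monthly_doses_leave_no_gap(depot_series, formulary):
    # three monthly doses at days 0, 10, 20: windows overlap, coverage is
    # their union [0, 50) and neither interval has uncovered days
    series = depot_series([0, 10, 20], drug_name="leuprorelin",
                          atc_code="L02AE02", dose_mg=3.75)
    ep = build_intervals(series, formulary)
    assert all(iv.uncovered_days == 0 for iv in ep.intervals)
    assert ep.coverage == [(series[0].dispense_date,
                            series[-1].dispense_date + timedelta(days=30))]


def test_without_carry_forward_unexpired_coverage_is_forfeit(depot_series, formulary):
    # a 6-month depot at day 0 still covers past a monthly dose at day 100;
    # carry-forward keeps that coverage, the strict convention discards it
    series = [
        depot_series([0], drug_name="leuprorelin", atc_code="L02AE02", dose_mg=22.5)[0],
        depot_series([100], drug_name="leuprorelin", atc_code="L02AE02", dose_mg=3.75)[0],
        depot_series([300], drug_name="leuprorelin", atc_code="L02AE02", dose_mg=3.75)[0],
    ]
    with_cf = build_intervals(series, formulary, EngineConfig(carry_forward=True))
    without = build_intervals(series, formulary, EngineConfig(carry_forward=False))
    assert with_cf.intervals[-1].uncovered_days == 300 - 183
    assert without.intervals[-1].uncovered_days == 300 - 130


def test_gap_below_threshold_is_not_an_off_period(depot_series, formulary):
    # 60 uncovered days < 91-day minimum gap
    ep = _episodes(depot_series([0, 151]), formulary)
    assert ep.intervals[0].uncovered_days == 60
    assert ep.off_periods == []


def test_trailing_gap_is_never_an_off_period(depot_series, formulary):
    # last dispensation followed by nothing: no re-initiation, no off period
    ep = _episodes(depot_series([0, 100, 200]), formulary)
    assert ep.off_periods == []
    assert ep.last_date == ep.dispensations[-1][0]


def test_multiple_units_extend_coverage_proportionally(depot_series, formulary):
    ep = build_intervals(depot_series([0, 200], n_units=2), formulary)
    assert ep.intervals[0].eld_days == 182
    assert ep.intervals[0].uncovered_days == 200 - 182


def test_same_day_duplicate_rows_merge_with_units_summed(depot_series, formulary):
    split = depot_series([0, 0, 250])
    merged = depot_series([0, 250], n_units=2)
    ep_split = build_intervals(split, formulary)
    ep_merged = build_intervals(merged, formulary)
    assert len(ep_split.dispensations) == 2
    assert ep_split.intervals[0].uncovered_days == ep_merged.intervals[0].uncovered_days


def test_unknown_dose_propagates_from_engine(depot_series, formulary):
    with pytest.raises(UnknownDose):
        build_intervals(depot_series([0], dose_mg=99), formulary)


def test_day_grid_single_window(depot_series, formulary):
    records = depot_series([0])
    start = records[0].dispense_date
    grid = day_grid_oracle(records, formulary, (start, start + timedelta(days=100)))
    assert grid[:91].all() and not grid[91:].any()


def test_day_grid_overlap_is_union(depot_series, formulary):
    records = depot_series([0, 30])
    start = records[0].dispense_date
    grid = day_grid_oracle(records, formulary, (start, start + timedelta(days=150)))
    assert grid[:121].all() and not grid[121:].any()


def _random_history(rng, depot_series):
    """Random patient history over up to ~7 years: mixed doses, units, gaps."""
    n = int(rng.integers(1, 15))
    offsets = np.cumsum(rng.integers(1, 260, size=n)) - 1
    choices = [
        ("goserelin", "L02AE03", 10.8),
        ("leuprorelin", "L02AE02", 3.75),
        ("leuprorelin", "L02AE02", 22.5),
        ("triptorelin", "L02AE04", 11.25),
        ("histrelin", "H01CA0", 50.0),
    ]
    records = []
    for off in offsets:
        drug, atc, dose = choices[int(rng.integers(0, len(choices)))]
        records.extend(
            depot_series([int(off)], drug_name=drug, atc_code=atc, dose_mg=dose,
                         n_units=int(rng.integers(1, 3)))
        )
    return records


def test_oracle_equivalence_on_fuzzed_histories(depot_series, formulary):
    """Interval arithmetic with carry-forward reproduces the day-grid
    oracle's maximal uncovered runs exactly, on 1,000 random histories."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        records = _random_history(rng, depot_series)
        min_gap = int(rng.choice([30, 91, 183]))
        ep = _episodes(records, formulary, min_gap_days=min_gap)
        got = [(o.start_date, o.end_date) for o in ep.off_periods]
        expected = oracle_off_periods(records, formulary, min_gap)
        assert got == expected


def test_off_period_count_monotone_in_min_gap(depot_series, formulary):
    rng = np.random.default_rng(7)
    for _ in range(100):
        records = _random_history(rng, depot_series)
        counts = []
        for gap in (30, 91, 150, 400, 10_000):
            ep = _episodes(records, formulary, min_gap_days=gap)
            counts.append(len(ep.off_periods))
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0 or max(
            iv.uncovered_days for iv in ep.intervals
        ) >= 10_000


def test_uncovered_days_conserve_off_days(depot_series, formulary):
    """Total uncovered days bound total off days; equality when every
    uncovered run clears the threshold (gap = 1 day)."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        records = _random_history(rng, depot_series)
        ep = _episodes(records, formulary, min_gap_days=91)
        assert sum(iv.uncovered_days for iv in ep.intervals) >= ep.total_off_days
        ep1 = _episodes(records, formulary, min_gap_days=1)
        assert sum(iv.uncovered_days for iv in ep1.intervals) == ep1.total_off_days


def test_translation_invariance(depot_series, formulary):
    rng = np.random.default_rng(5)
    records = _random_history(rng, depot_series)
    shifted = [
        type(r)(**{**r.__dict__, "dispense_date": r.dispense_date + timedelta(days=37)})
        for r in records
    ]
    ep, ep_shift = (_episodes(r, formulary) for r in (records, shifted))
    assert ep.span_days == ep_shift.span_days
    assert [o.duration_days for o in ep.off_periods] == [
        o.duration_days for o in ep_shift.off_periods
    ]
    for a, b in zip(ep.off_periods, ep_shift.off_periods):
        assert b.start_date - a.start_date == timedelta(days=37)
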