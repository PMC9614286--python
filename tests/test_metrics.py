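"""Prevalence estimators, %IAD, off-period summaries and the chi-square test."""

import math
from datetime import date

import numpy as np
import pytest

from iadprev import (
    annual_p_iad,
    build_episodes,
    chi_square_independence,
    global_p_iad,
    mean_annual_p_iad,
    offperiod_summary,
    percent_iad,
    prevalence_from_counts,
    treated_in_year,
    wilson_ci,
)
from iadprev.errors import (
    DegenerateTable,
    EmptyStratumWarning,
    FirstYearExcluded,
    UndefinedPercent,
    UndefinedPrevalence,
)
from iadprev.metrics import SCOPE_ALL, SCOPE_IAD, intermittent_in_year


@pytest.fixture()
def toy_episodes(depot_series, formulary):
    """Ten patients, two with a single off period overlapping 2013."""

    def patient(pid, offsets, origin, **kwargs):
        return depot_series(offsets, origin=origin, patient_id=pid, **kwargs)

    records = []
    for i in range(8):  # continuous: quarterly 91-day depots through 2012-2014
        records += patient(f"C{i}", [91 * k for k in range(9)], date(2012, 1, 15))
    # intermittent: gap of ~200 days uncovered inside 2013
    records += patient("I0", [0, 91, 382, 473], date(2012, 6, 1))
    records += patient("I1", [0, 91, 382, 473], date(2012, 8, 1))
    return build_episodes(records, formulary)


def test_six_month_depot_spans_year_boundary(depot_series, formulary):
    eps = build_episodes(
        depot_series([0], origin=date(2013, 12, 1), drug_name="leuprorelin",
                     atc_code="L02AE02", dose_mg=22.5),
        formulary,
    )
    assert treated_in_year(eps, 2013) == {"P1"}
    assert treated_in_year(eps, 2014) == {"P1"}
    with pytest.warns(EmptyStratumWarning):
        assert treated_in_year(eps, 2015) == set()


def test_coverage_ending_new_years_day_counts_previous_year_only(depot_series, formulary):
    # 91-day depot on 2014-10-02 covers through 2014-12-31; 2015-01-01 is bare
    eps = build_episodes(depot_series([0], origin=date(2014, 10, 2)), formulary)
    ep = next(iter(eps.values()))
    assert ep.coverage == [(date(2014, 10, 2), date(2015, 1, 1))]
    assert treated_in_year(eps, 2014) == {"P1"}
    with pytest.warns(EmptyStratumWarning):
        assert treated_in_year(eps, 2015) == set()


def test_annual_prevalence_direct_ratio(toy_episodes):
    est = annual_p_iad(toy_episodes, 2013)
    assert est.n_treated == 10
    assert est.n_intermittent == 2
    assert est.p_iad == pytest.approx(0.2)
    assert est.ci_low <= est.p_iad <= est.ci_high


def test_no_off_periods_gives_zero_prevalence(depot_series, formulary):
    eps = build_episodes(
        depot_series([0, 91, 182, 273], origin=date(2012, 2, 1)), formulary
    )
    est = annual_p_iad(eps, 2013)
    assert est.p_iad == 0 and est.ci_low == 0


def test_first_year_refused_without_override(toy_episodes):
    with pytest.raises(FirstYearExcluded):
        annual_p_iad(toy_episodes, 2012)
    est = annual_p_iad(toy_episodes, 2012, include_first_year=True)
    assert est.n_treated == 10


def test_global_share_matches_pooled_definition(toy_episodes):
    est = global_p_iad(toy_episodes)
    assert est.n_treated == 10 and est.n_intermittent == 2
    # pooled ever-intermittent fraction equals the global estimate exactly
    ever = {p for p, e in toy_episodes.items() if e.is_intermittent}
    assert est.p_iad == len(ever) / len(toy_episodes)


def test_global_share_printed_study_counts():
    est = prevalence_from_counts(7489, 44264)
    assert round(est.p_iad * 100) == 17


def test_mean_annual_from_values():
    printed = [0.082, 0.084, 0.072, 0.054, 0.036]
    assert round(mean_annual_p_iad(printed) * 100, 1) == 6.6
    assert mean_annual_p_iad([0.3, 0.3]) == pytest.approx(0.3)
    assert mean_annual_p_iad([0.0, 0.5]) == pytest.approx(0.25)


def test_mean_annual_from_episodes_matches_by_hand(toy_episodes):
    by_hand = np.mean([annual_p_iad(toy_episodes, y).p_iad for y in (2013, 2014)])
    assert mean_annual_p_iad(toy_episodes, [2013, 2014]) == pytest.approx(by_hand)


def test_percent_iad_denominator_scopes(depot_series, formulary):
    # patient S: span 365, one 100-day... use 182-day gap to clear threshold
    a = depot_series([0, 91, 374, 465], origin=date(2012, 1, 1), patient_id="A")
    b = depot_series([0, 91, 182, 273, 364, 455], origin=date(2012, 1, 1),
                     patient_id="B")
    eps = build_episodes(a + b, formulary)
    off = eps["A"].total_off_days
    assert off == 374 - 182  # one off period of 192 days
    span_a, span_b = eps["A"].span_days, eps["B"].span_days
    assert percent_iad(eps, scope=SCOPE_ALL).percent_iad == pytest.approx(
        off / (span_a + span_b)
    )
    assert percent_iad(eps, scope=SCOPE_IAD).percent_iad == pytest.approx(off / span_a)
    assert percent_iad(eps).percent_iad <= percent_iad(eps, scope=SCOPE_IAD).percent_iad


def test_percent_iad_zero_without_off_periods(depot_series, formulary):
    eps = build_episodes(depot_series([0, 91]), formulary)
    assert percent_iad(eps).percent_iad == 0


def test_percent_iad_undefined_for_zero_span(depot_series, formulary):
    eps = build_episodes(depot_series([0]), formulary)
    with pytest.raises(UndefinedPercent):
        percent_iad(eps)


def test_offperiod_summary_quantiles_by_hand(depot_series, formulary):
    # four off periods of 120, 150, 180 and 400 days (via tailored gaps)
    records = []
    for i, gap in enumerate([120, 150, 180, 400]):
        records += depot_series([0, 91 + gap, 182 + gap],
                                origin=date(2012, 1, 1 + i), patient_id=f"G{i}")
    eps = build_episodes(records, formulary)
    s = offperiod_summary(eps)
    days = np.array([120, 150, 180, 400])
    q1, med, q3 = np.percentile(days, [25, 50, 75])
    assert s.n_off_periods == 4
    assert s.median_months == pytest.approx(med / 30.44)
    assert s.iqr_months == pytest.approx((q3 - q1) / 30.44)
    assert s.min_months == pytest.approx(120 / 30.44)
    assert s.max_months == pytest.approx(400 / 30.44)


def test_offperiod_summary_single_period_has_zero_iqr(depot_series, formulary):
    eps = build_episodes(depot_series([0, 300, 391]), formulary)
    s = offperiod_summary(eps)
    assert s.n_off_periods == 1 and s.iqr_months == 0


def test_offperiod_summary_warns_on_empty_stratum(depot_series, formulary):
    eps = build_episodes(depot_series([0, 91]), formulary)
    with pytest.warns(EmptyStratumWarning):
        s = offperiod_summary(eps)
    assert s.n_off_periods == 0 and math.isnan(s.median_months)


def test_wilson_interval_against_closed_form():
    k, n, z = 10, 100, 1.959963984540054
    p = k / n
    centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = (z / (1 + z**2 / n)) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    low, high = wilson_ci(k, n)
    assert low == pytest.approx(centre - half, abs=1e-10)
    assert high == pytest.approx(centre + half, abs=1e-10)


def test_wilson_boundaries():
    assert wilson_ci(0, 100)[0] == 0
    assert wilson_ci(100, 100)[1] == 1
    with pytest.raises(UndefinedPrevalence):
        wilson_ci(0, 0)


def test_chi_square_matches_2x2_closed_form():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b, c, d = rng.integers(1, 200, size=4)
        stat, dof, p = chi_square_independence([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed)
        assert dof == 1


def test_chi_square_identical_proportions_is_null():
    stat, dof, p = chi_square_independence([[30, 70], [60, 140]])
    assert stat == pytest.approx(0)
    assert p == pytest.approx(1)


def test_chi_square_extreme_imbalance_tiny_p():
    _, _, p = chi_square_independence([[50, 0], [0, 50]])
    assert p < 1e-4


def test_chi_square_degenerate_tables():
    with pytest.raises(DegenerateTable):
        chi_square_independence([[0, 0], [5, 5]])
    with pytest.raises(DegenerateTable):
        chi_square_independence([[1, 2, 3]])


def test_region_stratification_conserves_counts(default_cohort, formulary):
    """Per-region numerators and denominators sum to the pooled ones."""
    from iadprev import apply_exclusions

    _, records, _ = default_cohort
    filtered, _ = apply_exclusions(records, formulary)
    eps = build_episodes(filtered, formulary)
    regions = sorted({e.region for e in eps.values()})
    for year in (2013, 2014):
        pooled_n = treated_in_year(eps, year)
        pooled_k = intermittent_in_year(eps, year) & pooled_n
        per_region_n = sum(len(treated_in_year(eps, year, r)) for r in regions)
        per_region_k = sum(
            len(intermittent_in_year(eps, year, r) & treated_in_year(eps, year, r))
            for r in regions
        )
        assert per_region_n == len(pooled_n)
        assert per_region_k == len(pooled_k)
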