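"""Prevalence and time-off-treatment estimators.

Two complementary estimators summarise intermittent androgen
deprivation (IAD) in a dispensation cohort:

* **P_IAD**, the annual prevalence of intermittency: the number of
  patients with at least one off-treatment period touching a calendar
  year, divided by the number of patients with any LHRH coverage in
  that year.  A Wilson score interval quantifies the sampling
  uncertainty.  The first calendar year of the observation window is
  excluded by default: intermittency opening before the window cannot
  be recognised, so its first-year estimate is systematically low.

* **%IAD**, the percentage of time off treatment: total off-period days
  (over patients with at least one off period) divided by the total
  days between first and last dispensation over the denominator
  population (all included patients by default).

The *global* ever-intermittent share (patients with ≥ 1 off period over
the whole window / all patients) is also provided; pooling years
overstates what any single year exhibits, since different patients pause
in different years, so the mean of annual prevalences is the headline
figure and the global share is reported alongside for context.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from datetime import date
from numbers import Real

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .episodes import PatientEpisodes
from .errors import (
    DegenerateTable,
    EmptyStratumWarning,
    FirstYearExcluded,
    UndefinedPercent,
    UndefinedPrevalence,
)
from .formulary import DurationPolicy

SCOPE_ALL = "all_patients"
SCOPE_IAD = "iad_patients_only"


@dataclass(frozen=True)
class PrevalenceEstimate:
    """P_IAD point estimate with confidence interval for one stratum."""

    year: int | str  # calendar year or "all"
    region: str  # region name or "all"
    n_treated: int
    n_intermittent: int
    p_iad: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PercentIAD:
    """%IAD: share of observed treatment span spent off treatment."""

    region: str
    scope: str
    off_days_total: int
    interval_days_total: int
    percent_iad: float


@dataclass(frozen=True)
class OffPeriodSummary:
    region: str
    n_off_periods: int
    median_months: float
    iqr_months: float
    min_months: float
    max_months: float


def _as_list(episodes) -> list[PatientEpisodes]:
    if isinstance(episodes, Mapping):
        return list(episodes.values())
    return list(episodes)


def _in_region(ep: PatientEpisodes, region: str | None) -> bool:
    return region is None or region == "all" or ep.region == region


def _year_bounds(year: int) -> tuple[date, date]:
    return date(year, 1, 1), date(year + 1, 1, 1)


def treated_in_year(episodes, year: int, region: str | None = None) -> set[str]:
    """Patients with >= 1 day of LHRH coverage in the calendar year.

    Coverage segments are half-open, so a depot whose effect ends
    exactly on 1 January does not make the patient treated in the new
    year.  A year with no coverage anywhere yields an empty set with an
    :class:`EmptyStratumWarning`.
    """
    y0, y1 = _year_bounds(year)
    out = set()
    for ep in _as_list(episodes):
        if not _in_region(ep, region):
            continue
        for s, e in ep.coverage:
            if s < y1 and e > y0:
                out.add(ep.patient_id)
                break
    if not out:
        warnings.warn(
            f"no patient treated in {year}" + (f" / {region}" if region else ""),
            EmptyStratumWarning,
            stacklevel=2,
        )
    return out


def intermittent_in_year(episodes, year: int, region: str | None = None) -> set[str]:
    """Patients with >= 1 off-period day inside the calendar year."""
    y0, y1 = _year_bounds(year)
    out = set()
    for ep in _as_list(episodes):
        if not _in_region(ep, region):
            continue
        for p in ep.off_periods:
            if p.start_date < y1 and p.end_date > y0:
                out.add(ep.patient_id)
                break
    return out


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if n <= 0:
        raise UndefinedPrevalence("Wilson interval undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    low, high = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    low = 0.0 if k == 0 else float(np.clip(low, 0, 1))
    high = 1.0 if k == n else float(np.clip(high, 0, 1))
    return low, high


def prevalence_from_counts(
    k: int,
    n: int,
    year: int | str = "all",
    region: str = "all",
    confidence: float = 0.95,
) -> PrevalenceEstimate:
    """Build a prevalence estimate from raw numerator/denominator counts."""
    if n <= 0:
        raise UndefinedPrevalence(f"no treated patients in stratum ({year}, {region})")
    low, high = wilson_ci(k, n, confidence)
    return PrevalenceEstimate(
        year=year, region=region, n_treated=n, n_intermittent=k,
        p_iad=k / n, ci_low=low, ci_high=high,
    )


def annual_p_iad(
    episodes,
    year: int,
    region: str | None = None,
    *,
    first_year: int | None = None,
    include_first_year: bool = False,
    confidence: float = 0.95,
) -> PrevalenceEstimate:
    """Annual prevalence of intermittency for one (year, region) stratum.

    ``first_year`` defaults to the earliest dispensation year in the
    cohort; requesting it raises :class:`FirstYearExcluded` unless
    ``include_first_year`` is set (the estimate is then returned but is
    known to be biased low).
    """
    eps = _as_list(episodes)
    if first_year is None and eps:
        first_year = min(ep.first_date.year for ep in eps)
    if year == first_year and not include_first_year:
        raise FirstYearExcluded(
            f"{year} is the first observation year; its P_IAD is underestimated "
            "(pass include_first_year=True to compute it anyway)"
        )
    denom = treated_in_year(eps, year, region)
    if not denom:
        raise UndefinedPrevalence(f"no treated patients in {year}" )
    numer = intermittent_in_year(eps, year, region) & denom
    return prevalence_from_counts(
        len(numer), len(denom), year=year,
        region=region or "all", confidence=confidence,
    )


def global_p_iad(episodes, region: str | None = None, confidence: float = 0.95) -> PrevalenceEstimate:
    """Ever-intermittent share over the whole window (pooled years).

    Note this overstates annual prevalence: patients pausing in
    different years all count once here.
    """
    eps = [ep for ep in _as_list(episodes) if _in_region(ep, region)]
    if not eps:
        raise UndefinedPrevalence("empty cohort")
    k = sum(1 for ep in eps if ep.is_intermittent)
    return prevalence_from_counts(k, len(eps), year="all",
                                  region=region or "all", confidence=confidence)


def mean_annual_p_iad(
    episodes_or_values,
    years: Sequence[int] | None = None,
    region: str | None = None,
    *,
    first_year: int | None = None,
    include_first_year: bool = False,
) -> float:
    """Unweighted mean of annual P_IAD values.

    Accepts either a cohort of episodes plus the years to average, or a
    plain sequence of already-computed annual prevalences (fractions).
    Strata whose prevalence is undefined (no treated patients) are
    dropped from the mean; if all are undefined, raises
    :class:`UndefinedPrevalence`.
    """
    values = list(episodes_or_values) if isinstance(episodes_or_values, Iterable) else None
    if values is not None and values and all(isinstance(v, Real) for v in values):
        return float(np.mean([float(v) for v in values]))
    if years is None:
        raise ValueError("years must be given when passing episodes")
    annual = []
    for y in years:
        try:
            est = annual_p_iad(
                episodes_or_values, y, region,
                first_year=first_year, include_first_year=include_first_year,
            )
        except UndefinedPrevalence:
            continue
        annual.append(est.p_iad)
    if not annual:
        raise UndefinedPrevalence("no stratum has a defined prevalence")
    return float(np.mean(annual))


def percent_iad(
    episodes,
    region: str | None = None,
    scope: str = SCOPE_ALL,
) -> PercentIAD:
    """%IAD: off-period days over treatment-span days.

    ``scope`` chooses the denominator population: every included
    patient (default) or only patients with at least one off period.
    """
    if scope not in (SCOPE_ALL, SCOPE_IAD):
        raise ValueError(f"unknown denominator scope {scope!r}")
    eps = [ep for ep in _as_list(episodes) if _in_region(ep, region)]
    off_days = sum(ep.total_off_days for ep in eps if ep.is_intermittent)
    if scope == SCOPE_IAD:
        span_days = sum(ep.span_days for ep in eps if ep.is_intermittent)
    else:
        span_days = sum(ep.span_days for ep in eps)
    if span_days == 0:
        raise UndefinedPercent("zero treatment-span denominator")
    return PercentIAD(
        region=region or "all", scope=scope,
        off_days_total=off_days, interval_days_total=span_days,
        percent_iad=off_days / span_days,
    )


def offperiod_summary(
    episodes,
    region: str | None = None,
    policy: DurationPolicy | None = None,
) -> OffPeriodSummary:
    """Median / IQR / range of off-period durations, in months.

    Quantiles use linear interpolation; IQR is Q3 − Q1.  An empty
    stratum returns NaN summaries with an :class:`EmptyStratumWarning`.
    """
    policy = policy or DurationPolicy()
    durations = [
        p.duration_days / policy.days_per_month
        for ep in _as_list(episodes)
        if _in_region(ep, region)
        for p in ep.off_periods
    ]
    if not durations:
        warnings.warn("no off periods in stratum", EmptyStratumWarning, stacklevel=2)
        return OffPeriodSummary(region or "all", 0, float("nan"), float("nan"),
                                float("nan"), float("nan"))
    arr = np.asarray(durations)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return OffPeriodSummary(
        region=region or "all",
        n_off_periods=len(durations),
        median_months=float(med),
        iqr_months=float(q3 - q1),
        min_months=float(arr.min()),
        max_months=float(arr.max()),
    )


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    ``table`` is an r × c count matrix with r, c >= 2.  A zero row or
    column marginal raises :class:`DegenerateTable`.
    Returns (statistic, degrees of freedom, p-value).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateTable(f"need an r x c table with r, c >= 2, got shape {arr.shape}")
    if (arr < 0).any():
        raise DegenerateTable("negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTable("zero marginal total")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def prevalence_table(
    episodes,
    years: Sequence[int],
    regions: Sequence[str] | None = None,
    *,
    first_year: int | None = None,
    include_first_year: bool = False,
) -> list[PrevalenceEstimate]:
    """All defined (year, region) prevalence estimates, regions plus pooled."""
    eps = _as_list(episodes)
    region_list = list(regions) if regions is not None else sorted({e.region for e in eps})
    out = []
    for y in years:
        for reg in [*region_list, None]:
            try:
                out.append(
                    annual_p_iad(eps, y, reg, first_year=first_year,
                                 include_first_year=include_first_year)
                )
            except (UndefinedPrevalence, FirstYearExcluded):
                continue
    return out
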