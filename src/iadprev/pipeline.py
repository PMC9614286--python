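"""End-to-end run: filters → episode engine → metrics → costs → tables.

One :func:`run_pipeline` call reproduces the whole analysis on a record
file and writes every result table as CSV, plus a machine-readable echo
of the resolved configuration so any output row is traceable to the
exact tunables that produced it.
"""

from __future__ import annotations

import json
import logging
import uuid
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .costs import annual_costs, costs_frame, mean_cost_per_dispensation
from .episodes import EngineConfig, build_episodes
from .errors import UndefinedPercent, UndefinedPrevalence
from .filters import apply_exclusions, qc_region_years
from .formulary import Formulary
from .metrics import (
    SCOPE_ALL,
    global_p_iad,
    mean_annual_p_iad,
    offperiod_summary,
    percent_iad,
    prevalence_table,
)
from .records import DispensationRecord

log = logging.getLogger("iadprev")


@dataclass
class RunConfig:
    """Resolved tunables of one pipeline run (echoed to run_config.json)."""

    min_gap_days: int = 91
    carry_forward: bool = True
    days_per_month: float = 30.44
    denominator_scope: str = SCOPE_ALL
    ci_method: str = "wilson"
    include_first_year: bool = False
    excluded_region_years: list = field(default_factory=list)
    formulary_path: str | None = None


def run_pipeline(
    records: list[DispensationRecord],
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict:
    """Execute the full analysis and write result tables under ``out_dir``.

    Returns a summary dict (headline numbers plus the run id).
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_id = uuid.uuid4().hex[:12]

    formulary = Formulary.load(config.formulary_path)
    engine_cfg = EngineConfig(
        min_gap_days=config.min_gap_days,
        carry_forward=config.carry_forward,
    )

    # --- exclusions (patient flowchart)
    filtered, exclusion_log = apply_exclusions(
        records, formulary, excluded_region_years=config.excluded_region_years
    )
    exclusion_log.to_json(out / "exclusion_log.json")
    (out / "exclusion_log.txt").write_text(exclusion_log.to_text(), encoding="utf-8")
    log.info(
        "patient flow: %d in -> %d under-18, %d antiandrogen-only, %d stratum-lost -> %d kept",
        exclusion_log.n_input_patients, exclusion_log.excluded_under18,
        exclusion_log.excluded_antiandrogen_only,
        exclusion_log.n_patients_lost_region_years, exclusion_log.n_final_patients,
    )
    qc_flags = qc_region_years(filtered)
    pd.DataFrame(qc_flags, columns=["region", "year", "n_records", "region_median"]).to_csv(
        out / "qc_region_years.csv", index=False
    )

    # --- episode reconstruction
    episodes = build_episodes(filtered, formulary, engine_cfg)
    ep_rows, off_rows = [], []
    for ep in episodes.values():
        age = (ep.first_date - ep.birth_date).days / 365.25
        ep_rows.append([ep.patient_id, ep.region, round(age, 1), len(ep.dispensations),
                        ep.span_days, len(ep.off_periods), ep.total_off_days])
        for p in ep.off_periods:
            off_rows.append([p.patient_id, p.start_date, p.end_date, p.duration_days])
    pd.DataFrame(
        ep_rows,
        columns=["patient_id", "region", "age_at_first", "n_dispensations",
                 "span_days", "n_off_periods", "total_off_days"],
    ).to_csv(out / "episodes_summary.csv", index=False)
    pd.DataFrame(
        off_rows, columns=["patient_id", "start", "end", "duration_days"]
    ).to_csv(out / "off_periods.csv", index=False)

    # --- prevalence metrics
    years = sorted({ep.first_date.year for ep in episodes.values()}
                   | {ep.last_date.year for ep in episodes.values()})
    first_year = min(years) if years else None
    estimates = prevalence_table(
        episodes, years, first_year=first_year,
        include_first_year=config.include_first_year,
    )
    prev_frame = pd.DataFrame(
        [
            [e.year, e.region, e.n_treated, e.n_intermittent, e.p_iad,
             e.ci_low, e.ci_high, e.year == first_year]
            for e in estimates
        ],
        columns=["year", "region", "n_treated", "n_intermittent",
                 "p_iad", "ci_low", "ci_high", "underestimated_first_year"],
    )
    prev_frame.to_csv(out / "prevalence.csv", index=False)

    regions = sorted({ep.region for ep in episodes.values()})
    pct_rows, off_summary_rows = [], []
    for reg in [*regions, None]:
        try:
            p = percent_iad(episodes, reg, scope=config.denominator_scope)
            pct_rows.append([p.region, p.scope, p.off_days_total,
                             p.interval_days_total, p.percent_iad])
        except UndefinedPercent:
            pass
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            s = offperiod_summary(episodes, reg)
        if s.n_off_periods:
            off_summary_rows.append([s.region, s.n_off_periods, s.median_months,
                                     s.iqr_months, s.min_months, s.max_months])
    pd.DataFrame(
        pct_rows,
        columns=["region", "scope", "off_days_total", "interval_days_total", "percent_iad"],
    ).to_csv(out / "percent_iad.csv", index=False)
    pd.DataFrame(
        off_summary_rows,
        columns=["region", "n_off_periods", "median_months", "iqr_months",
                 "min_months", "max_months"],
    ).to_csv(out / "offperiod_summary.csv", index=False)

    # --- cost accounting
    for name, keys in [
        ("costs_by_year_class.csv", ("year", "drug_class")),
        ("costs_by_year_region.csv", ("year", "region")),
        ("costs_by_year_drug.csv", ("year", "drug")),
    ]:
        summaries, _ = annual_costs(
            filtered, group_by=keys,
            excluded_region_years=config.excluded_region_years,
        )
        costs_frame(summaries).to_csv(out / name, index=False)

    # --- headline summary + config echo
    summary: dict = {"run_id": run_id, "version": __version__,
                     "n_patients": len(episodes)}
    try:
        g = global_p_iad(episodes)
        summary["global_p_iad"] = g.p_iad
    except UndefinedPrevalence:
        summary["global_p_iad"] = None
    try:
        later_years = [y for y in years if y != first_year]
        summary["mean_annual_p_iad"] = mean_annual_p_iad(
            episodes, later_years, first_year=first_year
        ) if later_years else None
    except UndefinedPrevalence:
        summary["mean_annual_p_iad"] = None
    try:
        summary["percent_iad"] = percent_iad(
            episodes, scope=config.denominator_scope
        ).percent_iad
    except UndefinedPercent:
        summary["percent_iad"] = None
    if years:
        mean_eur, sd_eur = mean_cost_per_dispensation(filtered, years[0])
        summary["cost_per_dispensation_first_year"] = [mean_eur, sd_eur]

    echo = {"run_id": run_id, "version": __version__, **asdict(config)}
    (out / "run_config.json").write_text(json.dumps(echo, indent=2), encoding="utf-8")
    (out / "summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
    return summary
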