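"""Plots and summary report over a finished pipeline run."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .errors import IOFailure

DECADE_BINS = list(range(40, 101, 10))


def plot_costs_by_year(costs_csv: str | Path, out_png: str | Path) -> bool:
    """Stacked bar chart of annual expenditure per drug."""
    table = _load(costs_csv)
    if table.empty:
        warnings.warn("cost table empty; chart skipped")
        return False
    pivot = table.pivot_table(index="year", columns="drug",
                              values="total_eur", aggfunc="sum").fillna(0)
    ax = (pivot / 1e6).plot(kind="bar", stacked=True, figsize=(8, 5))
    ax.set_xlabel("year")
    ax.set_ylabel("expenditure (million €)")
    ax.set_title("Hormonal-therapy expenditure per drug and year")
    plt.tight_layout()
    plt.savefig(out_png)
    plt.close()
    return True


def plot_age_distribution(episodes_csv: str | Path, out_png: str | Path) -> bool:
    """Decade-binned age histogram split by regimen (intermittent vs continuous).

    Annotates the shares of patients older than 70 and 80 years.
    """
    table = _load(episodes_csv)
    if table.empty:
        warnings.warn("episode table empty; chart skipped")
        return False
    fig, ax = plt.subplots(figsize=(8, 5))
    groups = {"IAD": table[table["n_off_periods"] > 0],
              "CAD": table[table["n_off_periods"] == 0]}
    for label, sub in groups.items():
        ax.hist(sub["age_at_first"], bins=DECADE_BINS, alpha=0.6, label=label)
    over70 = (table["age_at_first"] > 70).mean() * 100
    over80 = (table["age_at_first"] > 80).mean() * 100
    ax.set_title(f"Age at first dispensation ({over70:.0f}% > 70 y, {over80:.0f}% > 80 y)")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("patients")
    ax.legend()
    plt.tight_layout()
    plt.savefig(out_png)
    plt.close()
    return True


def plot_prevalence_trend(prevalence_csv: str | Path, out_png: str | Path) -> bool:
    """Annual P_IAD per region, with Wilson confidence bands."""
    table = _load(prevalence_csv)
    if table.empty:
        warnings.warn("prevalence table empty; chart skipped")
        return False
    fig, ax = plt.subplots(figsize=(8, 5))
    for region, sub in table.groupby("region"):
        sub = sub.sort_values("year")
        ax.plot(sub["year"], sub["p_iad"] * 100, marker="o", label=region)
        ax.fill_between(sub["year"], sub["ci_low"] * 100, sub["ci_high"] * 100, alpha=0.15)
    ax.set_xlabel("year")
    ax.set_ylabel("P_IAD (%)")
    ax.set_title("Annual prevalence of intermittent androgen deprivation")
    ax.legend()
    plt.tight_layout()
    plt.savefig(out_png)
    plt.close()
    return True


def render_report(run_dir: str | Path) -> list[Path]:
    """Render all charts for a pipeline output directory.

    Missing tables raise :class:`IOFailure` naming the absent file;
    empty tables skip their chart with a warning.
    """
    run_dir = Path(run_dir)
    produced = []
    jobs = [
        ("costs_by_year_drug.csv", "costs_by_year.png", plot_costs_by_year),
        ("episodes_summary.csv", "age_distribution.png", plot_age_distribution),
        ("prevalence.csv", "prevalence_trend.png", plot_prevalence_trend),
    ]
    for table_name, png_name, fn in jobs:
        table = run_dir / table_name
        if not table.exists():
            raise IOFailure(f"missing table {table}")
        if fn(table, run_dir / png_name):
            produced.append(run_dir / png_name)
    return produced


def _load(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
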