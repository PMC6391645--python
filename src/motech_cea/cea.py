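"""Incremental cost-effectiveness ratios, threshold verdicts and budget
context.

The comparator is the status quo (zero incremental cost and effect), so
incremental costs and effects are the program's own streams.  Ratios are
only defined when the effect denominator is positive; a year with cost
but no effect yields a typed "undefined" record rather than an infinity.
Verdicts follow the 1x / 3x GDP-per-capita convention: an ICER below one
times per-capita income is highly cost-effective, below three times is
cost-effective, and boundaries fall to the weaker class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .impact import ImpactResult


@dataclass(frozen=True)
class ICERRecord:
    scope: str                      # "year:<k>" or "cumulative"
    incremental_cost: float         # 2014 USD
    dalys_averted: float
    deaths_averted: float
    cost_per_daly: float | None     # None when undefined
    cost_per_death: float | None
    defined: bool
    reason: str = ""


VERDICTS = ("highly cost-effective", "cost-effective", "not cost-effective")


def icer(incremental_cost: float, dalys_averted: float,
         deaths_averted: float = float("nan"),
         scope: str = "cumulative") -> ICERRecord:
    """Ratio of incremental cost to DALYs (and deaths) averted."""
    if dalys_averted > 0:
        cpd = incremental_cost / dalys_averted
        cpdeath = (incremental_cost / deaths_averted
                   if deaths_averted and deaths_averted > 0 else None)
        return ICERRecord(scope, incremental_cost, dalys_averted,
                          deaths_averted, cpd, cpdeath, True)
    reason = ("no effect" if incremental_cost > 0 else "no cost, no effect")
    return ICERRecord(scope, incremental_cost, dalys_averted,
                      deaths_averted, None, None, False,
                      reason=f"undefined ({reason})")


def icer_table(cost_stream: pd.DataFrame, impact: ImpactResult,
               horizon_years: int = 10) -> list[ICERRecord]:
    """Per-year and cumulative ICERs from aligned cost/impact streams."""
    cost_by_year = cost_stream.groupby("year")["usd_2014"].sum()
    deaths_by_year = (impact.deaths_averted.groupby("year")
                      ["deaths_averted"].sum())
    records = []
    for y in range(1, horizon_years + 1):
        records.append(icer(
            float(cost_by_year.get(y, 0.0)),
            float(impact.dalys.get(y, 0.0)),
            float(deaths_by_year.get(y, 0.0)),
            scope=f"year:{y}"))
    records.append(icer(
        float(cost_by_year.sum()),
        float(impact.dalys.sum()),
        float(deaths_by_year.sum()),
        scope="cumulative"))
    return records


def classify(icer_value: float, per_capita_income: float) -> str:
    """Threshold verdict at 1x / 3x per-capita income per DALY averted."""
    if icer_value <= 0 or per_capita_income <= 0:
        raise ValueError("icer value and income must be positive")
    if icer_value < per_capita_income:
        return "highly cost-effective"
    if icer_value < 3.0 * per_capita_income:
        return "cost-effective"
    return "not cost-effective"


def budget_share(annual_cost_per_district: float, national_budget: float,
                 primary_care_fraction: float, n_districts: int) -> float:
    """Annual per-district program cost as a percent of the per-district
    primary-care budget allocation."""
    if min(national_budget, primary_care_fraction, n_districts) <= 0:
        raise ValueError("budget, fraction and district count must be "
                         "positive")
    per_district_budget = (national_budget * primary_care_fraction
                          / n_districts)
    return 100.0 * annual_cost_per_district / per_district_budget


def write_icers(records: list[ICERRecord], outdir: str | Path,
                per_capita_income: float | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        verdict = ""
        if r.defined and per_capita_income:
            verdict = classify(r.cost_per_daly, per_capita_income)
        rows.append({
            "scope": r.scope,
            "incremental_cost": r.incremental_cost,
            "dalys": r.dalys_averted,
            "cost_per_daly": "" if r.cost_per_daly is None
                             else r.cost_per_daly,
            "cost_per_death": "" if r.cost_per_death is None
                              else r.cost_per_death,
            "status": "defined" if r.defined else r.reason,
            "verdict": verdict,
        })
    path = outdir / "icers.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
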