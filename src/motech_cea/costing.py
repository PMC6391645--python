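"""Ingredients-based program costing over the phased rollout.

Turns the cost-ingredient inventory plus the three-year rollout schedule
into a district-by-year economic cost stream in 2014 USD.  Conventions:

* Every ingredient amount is a 10-year aggregate for the full reference
  rollout (170 districts; 1,347 implementation district-years from the
  45x9 + 67x8 + 58x7 cohort staggering).  Per-district rates are these
  aggregates divided by the *fixed* reference divisors, so the printed
  per-district rows (development 4,110; start-up 44,138; implementation
  17,918 per year) fall out exactly and adding districts to a schedule can
  only add cost.
* Development and start-up are one-time activities booked in a district's
  first active year (months 1-6 and 7-12 respectively); implementation
  recurs every following year through the horizon.
* Items with a variable driver (per_facility, per_nurse,
  per_enrollee_year) scale linearly with the district's counts relative to
  the Gomoa West anchor; lump/central items are spread evenly across
  participating districts.
* Raw local-currency outlays are converted at month-appropriate exchange
  rates and inflated to 2014 USD by the CPI ratio; capital outlays are
  annualized with the standard equivalent-annual-cost annuity factor at
  3 percent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import (
    CPI_BASE_YEAR,
    CostItem,
    District,
    GOMOA_WEST,
    HORIZON_YEARS,
    N_DISTRICTS_NATIONAL,
    PHASES,
    REFERENCE_COST_ITEMS,
    REFERENCE_CPI,
    REFERENCE_FX,
    REFERENCE_ROLLOUT_PLAN,
    REGIONS,
)

N_PERIODS = 6  # half-years over the 3-year rollout


# --------------------------------------------------------------------------
# Currency / price-level adjustment and capital annualization
# --------------------------------------------------------------------------

def adjust_to_base_year(
    raw_amount: float,
    currency: str,
    month: str,
    fx: dict[str, float] | None = None,
    cpi: dict[int, float] | None = None,
) -> float:
    """Convert a raw outlay to base-year (2014) USD.

    ``month`` is "YYYY-MM".  Non-USD amounts divide by that month's
    local-per-USD rate; all amounts are then scaled by
    cpi[2014]/cpi[year].  Missing months or years raise LookupError —
    never silent interpolation.
    """
    fx = REFERENCE_FX if fx is None else fx
    cpi = REFERENCE_CPI if cpi is None else cpi
    year = int(month[:4])
    if currency.upper() == "USD":
        usd = float(raw_amount)
    else:
        if month not in fx:
            raise LookupError(f"no FX rate for month {month!r}")
        usd = float(raw_amount) / fx[month]
    if year not in cpi or CPI_BASE_YEAR not in cpi:
        raise LookupError(f"no CPI entry for year {year}")
    return usd * cpi[CPI_BASE_YEAR] / cpi[year]


def annualize(amount: float, lifespan_years: float, r: float) -> float:
    """Equivalent annual cost of a capital outlay.

    amount * r / (1 - (1+r)^-lifespan); the r -> 0 limit is straight-line
    amount / lifespan.
    """
    if lifespan_years < 1:
        raise ValueError("lifespan_years must be >= 1")
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    if r == 0:
        return amount / lifespan_years
    return amount * r / (1.0 - (1.0 + r) ** (-lifespan_years))


# --------------------------------------------------------------------------
# Rollout schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RolloutSchedule:
    """Concrete district-to-start-period assignment (periods 1..6)."""

    entries: tuple[tuple[str, int], ...]  # (district_id, start_period)

    def start_years(self) -> dict[str, int]:
        """Calendar program year (1..3) each district becomes active."""
        return {d: (p + 1) // 2 for d, p in self.entries}

    def cumulative_active(self) -> list[int]:
        """Districts with program costs by the end of each period."""
        counts = [0] * N_PERIODS
        for _, p in self.entries:
            counts[p - 1] += 1
        return list(np.cumsum(counts))

    def implementation_district_years(self, horizon: int) -> int:
        return sum(max(0, horizon - y) for y in self.start_years().values())


def expand_rollout(
    plan: dict[str, tuple[int, ...]] | None,
    registry: pd.DataFrame,
) -> RolloutSchedule:
    """Assign concrete registry districts to the plan's start periods.

    ``plan`` maps region -> new districts per half-year period.  Districts
    are taken from the registry in district_id order within each region;
    a plan demanding more districts than a region has is rejected.
    """
    plan = REFERENCE_ROLLOUT_PLAN if plan is None else plan
    entries: list[tuple[str, int]] = []
    for region, counts in plan.items():
        if len(counts) != N_PERIODS:
            raise ValueError(f"plan for {region!r} must have "
                             f"{N_PERIODS} periods")
        avail = registry.loc[registry["region"] == region, "district_id"]
        avail = sorted(avail.tolist())
        need = sum(counts)
        if need > len(avail):
            raise ValueError(
                f"plan needs {need} districts in {region!r}, registry "
                f"has {len(avail)}")
        i = 0
        for period, c in enumerate(counts, start=1):
            for _ in range(c):
                entries.append((avail[i], period))
                i += 1
    return RolloutSchedule(tuple(sorted(entries)))


def districts_covered_percent(schedule: RolloutSchedule,
                              n_national: int = N_DISTRICTS_NATIONAL
                              ) -> float:
    """Share of the country's districts the rollout reaches, in percent."""
    return 100.0 * len(schedule.entries) / n_national


# --------------------------------------------------------------------------
# Reference divisors (derived from the reference plan, not hard-coded)
# --------------------------------------------------------------------------

def _reference_divisors(horizon: int = HORIZON_YEARS) -> tuple[int, int]:
    starts: list[int] = []
    for counts in REFERENCE_ROLLOUT_PLAN.values():
        for period, c in enumerate(counts, start=1):
            starts.extend([(period + 1) // 2] * c)
    n = len(starts)
    impl_years = sum(horizon - y for y in starts)
    return n, impl_years


REF_N_DISTRICTS, REF_IMPL_DISTRICT_YEARS = _reference_divisors()


# --------------------------------------------------------------------------
# Cost stream
# --------------------------------------------------------------------------

def _scaling(item: CostItem, row: pd.Series, anchor: District) -> float:
    if item.driver in ("lump_total", "per_district"):
        return 1.0
    if item.driver == "per_facility":
        return ((row["n_chps"] + row["n_health_centers"])
                / (anchor.n_chps + anchor.n_health_centers))
    if item.driver == "per_nurse":
        return row["n_nurses"] / anchor.n_nurses
    if item.driver == "per_enrollee_year":
        # enrollees track the annual birth cohort; with a common crude
        # birth rate this is population relative to the anchor
        return row["population"] / anchor.population
    raise KeyError(f"unresolvable driver {item.driver!r}")


def compute_cost_stream(
    items: tuple[CostItem, ...] | list[CostItem],
    schedule: RolloutSchedule,
    registry: pd.DataFrame,
    horizon_years: int = HORIZON_YEARS,
    anchor: District = GOMOA_WEST,
    discount_rate: float = 0.03,
) -> pd.DataFrame:
    """District-by-year-by-phase cost cells in 2014 USD.

    Returns a DataFrame (district_id, year, phase, usd_2014).  Development
    and start-up post in the district's first active year; implementation
    posts in every later year through the horizon.
    """
    reg = registry.set_index("district_id")
    missing = [d for d, _ in schedule.entries if d not in reg.index]
    if missing:
        raise ValueError(f"scheduled districts absent from registry: "
                         f"{missing[:5]}")
    start_years = schedule.start_years()

    dev_items = [i for i in items if i.phase == "development"]
    su_items = [i for i in items if i.phase == "start-up"]
    impl_items = [i for i in items if i.phase == "implementation"]

    rows: list[tuple[str, int, str, float]] = []
    for did, y0 in start_years.items():
        r = reg.loc[did]
        for item in dev_items:
            rows.append((did, y0, "development",
                         item.amount_2014usd / REF_N_DISTRICTS
                         * _scaling(item, r, anchor)))
        for item in su_items:
            rows.append((did, y0, "start-up",
                         item.amount_2014usd / REF_N_DISTRICTS
                         * _scaling(item, r, anchor)))
        for year in range(y0 + 1, horizon_years + 1):
            for item in impl_items:
                rows.append((did, year, "implementation",
                             item.amount_2014usd / REF_IMPL_DISTRICT_YEARS
                             * _scaling(item, r, anchor)))
    df = pd.DataFrame(rows, columns=["district_id", "year", "phase",
                                     "usd_2014"])
    df = (df.groupby(["district_id", "year", "phase"], as_index=False)
            ["usd_2014"].sum())
    df.attrs["discount_rate"] = discount_rate
    return df


def per_district_annual_rates(
    items: tuple[CostItem, ...] | list[CostItem] = REFERENCE_COST_ITEMS,
) -> dict[str, float]:
    """Per-district cost rates implied by the reference divisors: the
    one-off development and start-up amounts and the annual
    implementation amount, plus their total."""
    subtotal = phase_subtotals(items)
    rates = {
        "development": subtotal["development"] / REF_N_DISTRICTS,
        "start-up": subtotal["start-up"] / REF_N_DISTRICTS,
        "implementation": (subtotal["implementation"]
                           / REF_IMPL_DISTRICT_YEARS),
    }
    rates["total"] = sum(rates.values())
    return rates


def phase_subtotals(
    items: tuple[CostItem, ...] | list[CostItem],
) -> dict[str, float]:
    out = {p: 0.0 for p in PHASES}
    for item in items:
        out[item.phase] += item.amount_2014usd
    return out


def phase_shares(
    items: tuple[CostItem, ...] | list[CostItem],
) -> dict[tuple[str, str], float]:
    """Activity share of its phase subtotal, as a fraction.

    Raises ZeroDivisionError-flavoured ValueError on an empty phase.
    """
    subtotals = phase_subtotals(items)
    shares: dict[tuple[str, str], float] = {}
    for item in items:
        denom = subtotals[item.phase]
        if denom <= 0:
            raise ValueError(f"zero subtotal for phase {item.phase!r}")
        key = (item.phase, item.activity)
        shares[key] = shares.get(key, 0.0) + item.amount_2014usd / denom
    return shares


def discounted_total(stream: pd.DataFrame, r: float | None = None) -> float:
    """Present value of the stream at end-of-year discounting (optional
    cross-year discounting; the headline totals are undiscounted sums)."""
    if r is None:
        r = stream.attrs.get("discount_rate", 0.03)
    w = (1.0 + r) ** (-stream["year"].to_numpy(dtype=float))
    return float((stream["usd_2014"].to_numpy() * w).sum())


def write_cost_outputs(stream: pd.DataFrame,
                       items: tuple[CostItem, ...] | list[CostItem],
                       outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p_stream = outdir / "cost_stream.csv"
    stream.to_csv(p_stream, index=False)
    summary = {
        "phase_subtotals": phase_subtotals(items),
        "per_district_annual_rates": per_district_annual_rates(items),
        "activity_shares": {
            f"{ph}:{act}": share
            for (ph, act), share in phase_shares(items).items()
        },
        "stream_total_usd_2014": float(stream["usd_2014"].sum()),
    }
    p_sum = outdir / "phase_summary.json"
    p_sum.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"cost_stream": p_stream, "phase_summary": p_sum}
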