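"""Coverage scale-up projection with breakpoint attenuation.

Intervention coverage is projected year by year from a baseline and a
program-attributable annual increment.  Gains slow as coverage saturates:
once start-of-year coverage reaches 75 percent the step is halved, at 90
percent it is halved again (a quarter of the nominal step), and coverage
can never exceed 99 percent.  The boundary convention — factors keyed to
start-of-year coverage with the 75/90 thresholds inclusive on the upper
side — is documented in the methods note.

District trajectories start the year the district enters implementation
(gains lag rollout by the development/start-up year), and the endline
effect is spread linearly over the first ``ramp_years`` implementation
years.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .reference import (
    HORIZON_YEARS,
    INTERVENTIONS,
    RAMP_YEARS,
    REFERENCE_BASELINE_COVERAGE,
)
from .costing import RolloutSchedule

COVERAGE_CAP = 99.0


@dataclass(frozen=True)
class CoverageTrajectory:
    intervention: str
    baseline: float          # percent
    annual_increment: float  # percentage points per year (nominal)
    values: tuple[float, ...]  # per program-year percent


def attenuation_factor(cov: float) -> float:
    """Step multiplier given start-of-year coverage (percent)."""
    if cov < 75.0:
        return 1.0
    if cov < 90.0:
        return 0.5
    return 0.25


def project_coverage(baseline: float, increment: float,
                     years: int) -> CoverageTrajectory:
    """Project coverage for ``years`` program years.

    Each year's value is the previous value plus the increment scaled by
    the attenuation factor at start-of-year coverage, capped at 99.
    """
    if not 0.0 <= baseline <= 100.0:
        raise ValueError("baseline must be within [0, 100]")
    if increment < 0:
        raise ValueError("coverage decline is not modelled")
    cov = min(baseline, COVERAGE_CAP)
    values = []
    for _ in range(years):
        cov = min(cov + increment * attenuation_factor(cov), COVERAGE_CAP)
        values.append(cov)
    return CoverageTrajectory("", baseline, increment, tuple(values))


def ramped_trajectory(baseline: float, total_effect: float,
                      ramp_years: int, years: int) -> tuple[float, ...]:
    """Coverage path when the endline effect accrues over ``ramp_years``
    equal nominal steps (each attenuated by the breakpoint rules), then
    holds."""
    if ramp_years < 1:
        raise ValueError("ramp_years must be >= 1")
    step = total_effect / ramp_years
    cov = min(baseline, COVERAGE_CAP)
    values = []
    for year in range(1, years + 1):
        if year <= ramp_years:
            cov = min(cov + step * attenuation_factor(cov), COVERAGE_CAP)
        values.append(cov)
    return tuple(values)


def build_coverage_table(
    schedule: RolloutSchedule,
    effects: dict[str, float] | None = None,
    baselines: dict[str, float] | None = None,
    horizon_years: int = HORIZON_YEARS,
    ramp_years: int = RAMP_YEARS,
) -> pd.DataFrame:
    """Per-district coverage by program year and intervention (percent).

    ``effects`` are endline coverage-point increases (e.g. sba: 11.0).
    Before a district's first implementation year coverage sits at
    baseline; from that year the ramped, attenuated path applies.
    """
    effects = dict(effects or {})
    baselines = dict(REFERENCE_BASELINE_COVERAGE if baselines is None
                     else baselines)
    start_years = schedule.start_years()
    # implementation starts the year after the start-up year; trajectories
    # only depend on the cohort start year, so compute one per cohort
    paths: dict[tuple[str, int], tuple[float, ...]] = {}
    rows = []
    for did, y0 in start_years.items():
        impl_start = y0 + 1
        for iv in INTERVENTIONS:
            base = baselines[iv]
            eff = float(effects.get(iv, 0.0))
            key = (iv, impl_start)
            if key not in paths:
                n_active = max(0, horizon_years - impl_start + 1)
                active = ramped_trajectory(base, eff, ramp_years, n_active)
                full = (base,) * (impl_start - 1) + active
                paths[key] = full[:horizon_years]
            for year, pct in enumerate(paths[key], start=1):
                rows.append((did, year, iv, pct))
    return pd.DataFrame(rows, columns=["district_id", "year",
                                       "intervention", "percent"])


def write_coverage(table: pd.DataFrame, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "coverage.csv"
    table.to_csv(path, index=False)
    return path
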