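"""Lives saved and DALYs averted from coverage gains.

A transparent attributable-risk engine stands in for the cohort software
used in the original forecast: for each district-year, intervention and
outcome (maternal death, under-five death, stillbirth),

    averted = D0 * a * e * (cov_t - cov_0)/100 / (1 - e * cov_0/100)

where D0 is the baseline death envelope, ``e`` the intervention's efficacy
against the outcome, ``a`` the affected fraction (the share of the
envelope the intervention can touch), and the denominator removes deaths
already prevented by baseline coverage so the estimate stays consistent
with partial baseline coverage.  Contributions sum over interventions.

DALYs are years of life lost only, continuously discounted:
``YLL = deaths * (1 - exp(-r*L)) / r`` at discount rate r and remaining
life expectancy L (65.5 years for child deaths and stillbirths, 36.5 for
maternal deaths by default; stillbirths can be excluded by config).

A calibration mode rescales each outcome's affected fractions by a common
factor so modelled 10-year totals reproduce user-supplied anchor totals;
the engine is linear in the affected fractions, so calibrated totals match
the anchors exactly (and rescaled fractions must remain <= 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import (
    DemographicParams,
    HORIZON_YEARS,
    INTERVENTIONS,
    OUTCOMES,
    REFERENCE_EFFECTIVENESS,
)


@dataclass(frozen=True)
class EffectivenessMatrix:
    """(efficacy, affected_fraction) per (intervention, outcome)."""

    entries: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(REFERENCE_EFFECTIVENESS))

    def __post_init__(self) -> None:
        for key, (e, a) in self.entries.items():
            if not (0.0 <= e <= 1.0 and 0.0 <= a <= 1.0):
                raise ValueError(
                    f"efficacy/affected fraction out of [0,1] for {key}")

    def scaled(self, factors: dict[str, float]) -> "EffectivenessMatrix":
        """Affected fractions multiplied by a per-outcome factor."""
        new = {}
        for (iv, oc), (e, a) in self.entries.items():
            a2 = a * factors.get(oc, 1.0)
            if a2 > 1.0 + 1e-9:
                raise ValueError(
                    f"calibration pushes affected fraction above 1 for "
                    f"({iv}, {oc}): {a2:.3f}")
            new[(iv, oc)] = (e, min(a2, 1.0))
        return EffectivenessMatrix(new)


@dataclass
class ImpactResult:
    """National-scale per-year deaths averted and discounted YLLs."""

    deaths_averted: pd.DataFrame  # columns: year, outcome, deaths_averted
    dalys: pd.Series              # indexed by year
    params: DemographicParams

    def totals_by_outcome(self) -> dict[str, float]:
        g = self.deaths_averted.groupby("outcome")["deaths_averted"].sum()
        return {o: float(g.get(o, 0.0)) for o in OUTCOMES}

    def total_lives_saved(self) -> float:
        return float(self.deaths_averted["deaths_averted"].sum())

    def total_dalys(self) -> float:
        return float(self.dalys.sum())


# --------------------------------------------------------------------------
# Core arithmetic
# --------------------------------------------------------------------------

def averted_fraction(cov0: float, cov_t: float, efficacy: float,
                     affected: float) -> float:
    """Share of the baseline envelope averted by a coverage move
    cov0 -> cov_t (both percent)."""
    denom = 1.0 - efficacy * cov0 / 100.0
    if denom <= 0:
        raise ValueError("efficacy x baseline coverage >= 100%: residual "
                         "mortality denominator non-positive")
    return affected * efficacy * (cov_t - cov0) / 100.0 / denom


def yll(deaths: float, remaining_years: float, r: float) -> float:
    """Discounted years of life lost: deaths * (1 - e^(-rL)) / r."""
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    if remaining_years <= 0:
        raise ValueError("remaining_years must be positive")
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    if r == 0:
        return deaths * remaining_years
    return deaths * (1.0 - math.exp(-r * remaining_years)) / r


def yll_per_death(params: DemographicParams) -> dict[str, float]:
    r, L = params.discount_rate, params.life_expectancy
    per = {
        "maternal": yll(1.0, params.maternal_remaining_years, r),
        "child": yll(1.0, L, r),
        "stillbirth": (yll(1.0, L, r)
                       if params.include_stillbirth_dalys else 0.0),
    }
    return per


# --------------------------------------------------------------------------
# Mortality envelope
# --------------------------------------------------------------------------

def mortality_envelope(registry: pd.DataFrame,
                       params: DemographicParams) -> pd.DataFrame:
    """Annual per-district live births and baseline deaths per outcome."""
    births = (registry["population"].to_numpy(dtype=float)
              * registry["crude_birth_rate"].to_numpy(dtype=float) / 1000.0)
    return pd.DataFrame({
        "district_id": registry["district_id"].to_numpy(),
        "live_births": births,
        "maternal": births * params.mmr / 100_000.0,
        "child": births * params.under5_mortality / 1000.0,
        "stillbirth": births * params.stillbirth_rate / 1000.0,
    })


# --------------------------------------------------------------------------
# Engine
# --------------------------------------------------------------------------

def deaths_averted(
    registry: pd.DataFrame,
    coverage_table: pd.DataFrame,
    eff: EffectivenessMatrix,
    params: DemographicParams,
    baselines: dict[str, float],
) -> pd.DataFrame:
    """Per district-year-outcome deaths averted, summed over interventions.

    ``coverage_table`` is the per-district table from the coverage stage
    (district_id, year, intervention, percent); ``baselines`` give cov_0
    per intervention in percent.
    """
    env = mortality_envelope(registry, params).set_index("district_id")
    missing = set(coverage_table["district_id"]) - set(env.index)
    if missing:
        raise ValueError(f"coverage table has districts absent from the "
                         f"registry: {sorted(missing)[:5]}")
    cov = coverage_table.copy()
    frames = []
    for (iv, oc), (e, a) in eff.entries.items():
        sub = cov[cov["intervention"] == iv]
        if sub.empty or e == 0.0 or a == 0.0:
            continue
        cov0 = baselines[iv]
        denom = 1.0 - e * cov0 / 100.0
        if denom <= 0:
            raise ValueError("efficacy x baseline coverage >= 100%")
        d0 = env.loc[sub["district_id"], oc].to_numpy()
        frac = a * e * (sub["percent"].to_numpy() - cov0) / 100.0 / denom
        frames.append(pd.DataFrame({
            "district_id": sub["district_id"].to_numpy(),
            "year": sub["year"].to_numpy(),
            "outcome": oc,
            "deaths_averted": d0 * np.maximum(frac, 0.0),
        }))
    if not frames:
        return pd.DataFrame(columns=["district_id", "year", "outcome",
                                     "deaths_averted"])
    out = pd.concat(frames, ignore_index=True)
    return (out.groupby(["district_id", "year", "outcome"], as_index=False)
               ["deaths_averted"].sum())


def calibration_factors(model_totals: dict[str, float],
                        anchors: dict[str, float]) -> dict[str, float]:
    """Per-outcome multipliers taking modelled 10-year totals onto the
    supplied anchors."""
    factors = {}
    for oc, target in anchors.items():
        got = model_totals.get(oc, 0.0)
        if got <= 0:
            raise ValueError(f"cannot calibrate {oc!r}: model total is 0")
        factors[oc] = target / got
    return factors


def calibrate_effectiveness(
    registry: pd.DataFrame,
    coverage_table: pd.DataFrame,
    eff: EffectivenessMatrix,
    params: DemographicParams,
    baselines: dict[str, float],
    anchors: dict[str, float],
) -> EffectivenessMatrix:
    """Scale affected fractions so 10-year totals hit ``anchors``."""
    base = deaths_averted(registry, coverage_table, eff, params, baselines)
    totals = base.groupby("outcome")["deaths_averted"].sum().to_dict()
    return eff.scaled(calibration_factors(totals, anchors))


def aggregate_impact(
    per_district: pd.DataFrame,
    params: DemographicParams,
    horizon_years: int = HORIZON_YEARS,
) -> ImpactResult:
    """Sum district results to national per-year totals and attach DALYs."""
    cols = {"year", "outcome", "deaths_averted"}
    if not cols <= set(per_district.columns):
        raise ValueError(f"per-district table must have columns {cols}")
    nat = (per_district.groupby(["year", "outcome"], as_index=False)
           ["deaths_averted"].sum())
    per = yll_per_death(params)
    nat["dalys"] = (nat["deaths_averted"]
                    * nat["outcome"].map(per).astype(float))
    dalys = nat.groupby("year")["dalys"].sum()
    dalys = dalys.reindex(range(1, horizon_years + 1), fill_value=0.0)
    return ImpactResult(
        deaths_averted=nat[["year", "outcome", "deaths_averted"]],
        dalys=dalys, params=params)


def write_impact(result: ImpactResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per = yll_per_death(result.params)
    table = result.deaths_averted.copy()
    table["dalys"] = [d * per[o] for d, o in
                      zip(table["deaths_averted"], table["outcome"])]
    p_csv = outdir / "impact.csv"
    table.to_csv(p_csv, index=False)
    summary = {
        "totals_by_outcome": result.totals_by_outcome(),
        "total_lives_saved": result.total_lives_saved(),
        "total_dalys": result.total_dalys(),
        "yll_per_death": per,
    }
    p_json = outdir / "impact_summary.json"
    p_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"impact": p_csv, "impact_summary": p_json}
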