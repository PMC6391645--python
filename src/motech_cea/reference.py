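"""Reference configuration for the MOTECH scale-up analysis.

The scale-up study costed the Mobile Technology for Community Health
(MOTECH) program — voice messaging to pregnant and postpartum women plus a
mobile client-data application for frontline nurses — from an ingredients
inventory built in Gomoa West district and a three-year national rollout
plan covering 170 of Ghana's 216 districts.  This module carries that
published reference configuration as plain data:

* the cost-ingredient table (activity, phase, level, 10-year amount in
  2014 USD, variable-cost driver),
* the rollout plan (new districts per region per half-year),
* the Gomoa West anchor district used to scale variable costs,
* demographic, coverage and effectiveness defaults for the lives-saved
  engine, and
* the published 10-year lives-saved anchors used by the engine's
  calibration mode.

Amounts are the published 10-year aggregates; per-district rates derive
from the fixed reference divisors (170 districts; 1347 implementation
district-years from the 45x9 + 67x8 + 58x7 cohort staggering).
"""

from __future__ import annotations

from dataclasses import dataclass, field


# --------------------------------------------------------------------------
# Anchor district (Gomoa West)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class District:
    """One district of the registry driving variable program costs."""

    district_id: str
    region: str
    population: int
    n_chps: int
    n_health_centers: int
    n_hospitals: int
    n_nurses: int
    crude_birth_rate: float  # births per 1000 population per year

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be positive")
        for f in ("n_chps", "n_health_centers", "n_hospitals", "n_nurses"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


#: Default national crude birth rate (births per 1000 population per year).
#: Chosen for internal consistency with ~3,100 maternal deaths per year at
#: an MMR of 380 per 100,000 live births on a population of 24.5 million.
DEFAULT_CRUDE_BIRTH_RATE = 33.0

#: Gomoa West: population 135,139; 17 CHPS facilities (1 per 7,949 people);
#: 4 health centers (1 per 33,785 people); 1 district hospital.  The nurse
#: count is not published; 2 nurses per frontline facility is assumed.
GOMOA_WEST = District(
    district_id="GOMOA_WEST",
    region="Central",
    population=135_139,
    n_chps=17,
    n_health_centers=4,
    n_hospitals=1,
    n_nurses=42,
    crude_birth_rate=DEFAULT_CRUDE_BIRTH_RATE,
)

#: Districts in the country overall (the rollout reaches 170 of them).
N_DISTRICTS_NATIONAL = 216


# --------------------------------------------------------------------------
# Cost-ingredient table
# --------------------------------------------------------------------------

PHASES = ("development", "start-up", "implementation")
DRIVERS = ("lump_total", "per_district", "per_facility", "per_nurse",
           "per_enrollee_year")
LEVELS = ("central", "regional", "district")


@dataclass(frozen=True)
class CostItem:
    """One ingredient of the program cost inventory.

    ``amount_2014usd`` is the 10-year aggregate for the full 170-district
    rollout in 2014 US dollars.  ``driver`` says how the item scales with
    district characteristics relative to the Gomoa West anchor.
    """

    activity: str
    phase: str
    level: str
    amount_2014usd: float
    driver: str = "per_district"
    capital: bool = False
    lifespan_years: float | None = None
    raw_amount: float | None = None
    incurred_month: str | None = None  # "YYYY-MM" in the source currency

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.driver not in DRIVERS:
            raise ValueError(f"unknown driver {self.driver!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.amount_2014usd < 0:
            raise ValueError("amount must be non-negative")
        if self.capital and (self.lifespan_years is None
                             or self.lifespan_years < 1):
            raise ValueError("capital items need lifespan_years >= 1")


def _ci(activity, phase, level, amount, driver="per_district", **kw):
    return CostItem(activity, phase, level, float(amount), driver, **kw)


#: The published cost inventory.  Development activities are central,
#: one-off amounts; start-up and implementation mix central and district
#: level.  The development line items sum to 674,142 against a published
#: subtotal of 698,647; the residual is carried explicitly as an
#: unallocated balancing entry so phase subtotals match the published ones.
REFERENCE_COST_ITEMS: tuple[CostItem, ...] = (
    # development (6 months per district, central level)
    _ci("Program design", "development", "central", 36_800, "lump_total"),
    _ci("Telecommunications", "development", "central", 23_480, "lump_total"),
    _ci("Technology", "development", "central", 16_907, "lump_total"),
    _ci("Personnel", "development", "central", 596_955, "lump_total"),
    _ci("Unallocated balance", "development", "central", 24_505, "lump_total"),
    # start-up (6 months per district)
    _ci("District profiling", "start-up", "district", 150_919),
    _ci("Content localization", "start-up", "central", 30_690, "lump_total"),
    _ci("Equipment", "start-up", "district", 2_471_799, "per_facility"),
    _ci("Customer support", "start-up", "central", 249_746, "lump_total"),
    _ci("Training", "start-up", "district", 2_406_578, "per_nurse"),
    _ci("Community mobilization", "start-up", "district", 627_638),
    _ci("Partnership building", "start-up", "regional", 10_449),
    _ci("Vehicle maintenance", "start-up", "district", 172_082),
    _ci("Office maintenance", "start-up", "central", 86_277, "lump_total"),
    _ci("Telecommunications", "start-up", "district", 77_166),
    _ci("Technology", "start-up", "central", 26_318, "lump_total"),
    _ci("Personnel & benefits", "start-up", "central", 1_193_847,
        "lump_total"),
    # implementation (annual, sustained)
    _ci("Technical groups", "implementation", "district", 17_810),
    _ci("Monitoring and evaluation", "implementation", "district", 1_700_567),
    _ci("Continued training", "implementation", "district", 2_140_605,
        "per_nurse"),
    # phone replacement (assumed 3-year handset life) + annual registers
    _ci("Equipment & materials", "implementation", "district", 4_928_480,
        "per_facility"),
    _ci("Vehicle maintenance", "implementation", "district", 1_078_131),
    _ci("Field office maintenance", "implementation", "district", 209_521),
    _ci("Office maintenance", "implementation", "central", 257_036,
        "lump_total"),
    _ci("Telecommunications", "implementation", "district", 2_343_275,
        "per_enrollee_year"),
    _ci("Technology maintenance", "implementation", "central", 241_582,
        "lump_total"),
    _ci("Personnel & benefits", "implementation", "central", 11_218_454,
        "lump_total"),
)


# --------------------------------------------------------------------------
# Rollout plan: new districts per region per half-year period (1..6)
# --------------------------------------------------------------------------

REGIONS = ("Western", "Central", "Greater Accra", "Volta", "Eastern",
           "Ashanti", "Brong-Ahafo", "Northern", "Upper East", "Upper West")

#: New districts starting per half-year period over the 3-year rollout.
REFERENCE_ROLLOUT_PLAN: dict[str, tuple[int, ...]] = {
    "Western":       (5, 5, 7, 0, 0, 0),
    "Central":       (5, 5, 7, 0, 0, 0),
    "Greater Accra": (5, 5, 0, 0, 0, 0),
    "Volta":         (0, 5, 5, 8, 0, 0),
    "Eastern":       (0, 5, 5, 5, 6, 0),
    "Ashanti":       (0, 5, 5, 5, 5, 7),
    "Brong-Ahafo":   (0, 0, 5, 5, 5, 7),
    "Northern":      (0, 0, 5, 5, 5, 5),
    "Upper East":    (0, 0, 0, 0, 5, 4),
    "Upper West":    (0, 0, 0, 0, 5, 4),
}

#: Planned district totals per region (sums to 170).
REGION_TOTALS: dict[str, int] = {
    r: sum(v) for r, v in REFERENCE_ROLLOUT_PLAN.items()
}


# --------------------------------------------------------------------------
# Epidemiological and economic defaults
# --------------------------------------------------------------------------

INTERVENTIONS = ("sba", "facility_delivery", "measles")
OUTCOMES = ("maternal", "child", "stillbirth")

#: Program-attributable coverage-point increases observed in the field
#: evaluation: skilled birth attendance +11, facility delivery +10,
#: measles immunization +6 percentage points.
REFERENCE_EFFECTS: dict[str, float] = {
    "sba": 11.0,
    "facility_delivery": 10.0,
    "measles": 6.0,
}

#: Baseline coverage (percent).  Skilled attendance ~70% (nearly 30% of
#: deliveries unattended); facility delivery and measles baselines are
#: national survey-era values, configurable.
REFERENCE_BASELINE_COVERAGE: dict[str, float] = {
    "sba": 70.0,
    "facility_delivery": 57.0,
    "measles": 89.0,
}


@dataclass(frozen=True)
class DemographicParams:
    """Mortality envelope rates and DALY parameters."""

    crude_birth_rate: float = DEFAULT_CRUDE_BIRTH_RATE  # per 1000 pop/yr
    mmr: float = 380.0           # maternal deaths per 100,000 live births
    under5_mortality: float = 49.0   # deaths per 1000 live births
    stillbirth_rate: float = 22.0    # per 1000 births
    discount_rate: float = 0.03      # per year
    life_expectancy: float = 65.5    # years, at-birth deaths
    maternal_remaining_years: float = 36.5  # 65.5 minus mean maternal age 29
    include_stillbirth_dalys: bool = True


#: Pre-calibration effectiveness defaults: (efficacy, affected_fraction)
#: per (intervention, outcome).  Efficacies are set generously and
#: affected fractions moderately so that calibration to the published
#: 10-year anchors keeps every affected fraction inside [0, 1].
REFERENCE_EFFECTIVENESS: dict[tuple[str, str], tuple[float, float]] = {
    ("sba", "maternal"): (0.95, 0.40),
    ("sba", "child"): (0.70, 0.30),
    ("sba", "stillbirth"): (0.85, 0.40),
    ("facility_delivery", "maternal"): (0.95, 0.40),
    ("facility_delivery", "child"): (0.70, 0.30),
    ("facility_delivery", "stillbirth"): (0.75, 0.40),
    ("measles", "child"): (0.85, 0.05),
}

#: Published 10-year lives-saved totals used as calibration anchors.
REFERENCE_LIVES_SAVED_ANCHORS: dict[str, float] = {
    "maternal": 6_298.0,
    "child": 33_797.0,
    "stillbirth": 19_811.0,
}

#: Published Year-2 lives-saved components (child / stillbirth / maternal).
REFERENCE_YEAR2_COMPONENTS: dict[str, float] = {
    "child": 288.0,
    "stillbirth": 152.0,
    "maternal": 43.0,
}

#: Context figures for threshold classification and budget-share analysis.
GNI_PER_CAPITA_USD = 1_480.0
HEALTH_BUDGET_USD = 264_500_000.0
PRIMARY_CARE_FRACTION = 0.72

#: Willingness-to-pay grid (USD per DALY averted) for the CEAC.
DEFAULT_WTP_GRID = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1480.0, 4440.0)

HORIZON_YEARS = 10
RAMP_YEARS = 2  # coverage effect spread linearly over first 2 program years


# --------------------------------------------------------------------------
# FX / CPI fixtures (synthetic; the study cites sources but not the rates)
# --------------------------------------------------------------------------

def _monthly_fx() -> dict[str, float]:
    # GHS per USD drifting from ~1.90 (Jan 2012) to ~3.20 (Dec 2014)
    rates = {}
    start, end = 1.90, 3.20
    months = [f"{y}-{m:02d}" for y in (2012, 2013, 2014)
              for m in range(1, 13)]
    n = len(months)
    for i, key in enumerate(months):
        rates[key] = round(start + (end - start) * i / (n - 1), 4)
    return rates


#: Synthetic month-by-month GHS-per-USD exchange rates, 2012-2014.
REFERENCE_FX: dict[str, float] = _monthly_fx()

#: Synthetic annual CPI for Ghana with 2014 = 100 (the base year).
REFERENCE_CPI: dict[int, float] = {2012: 78.0, 2013: 87.8, 2014: 100.0}
CPI_BASE_YEAR = 2014
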