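"""Ingredients costing: currency adjustment, annualization, rollout
expansion, the cost stream and phase shares."""

import numpy as np
import pandas as pd
import pytest

from motech_cea import synth
from motech_cea.costing import (
    RolloutSchedule,
    adjust_to_base_year,
    annualize,
    compute_cost_stream,
    districts_covered_percent,
    expand_rollout,
    per_district_annual_rates,
    phase_shares,
    phase_subtotals,
)
from motech_cea.reference import REFERENCE_COST_ITEMS


class TestAdjustToBaseYear:
    def test_usd_in_base_year_unchanged(self):
        assert adjust_to_base_year(250.0, "USD", "2014-06") == 250.0

    def test_hand_arithmetic_fx_and_cpi(self):
        # raw=100 local at fx 2.0, cpi ratio 2014/2013 = 1.10 -> 55.00
        fx = {"2013-05": 2.0}
        cpi = {2013: 100.0, 2014: 110.0}
        out = adjust_to_base_year(100.0, "GHS", "2013-05", fx=fx, cpi=cpi)
        assert out == pytest.approx(55.0)

    def test_missing_month_is_lookup_error(self):
        with pytest.raises(LookupError):
            adjust_to_base_year(10.0, "GHS", "2011-01",
                                fx={"2013-05": 2.0}, cpi={2014: 100.0})

    def test_missing_cpi_year_is_lookup_error(self):
        with pytest.raises(LookupError):
            adjust_to_base_year(10.0, "USD", "2009-01",
                                cpi={2014: 100.0})


class TestAnnualize:
    def test_zero_discount_is_straight_line(self):
        assert annualize(1000.0, 10, 0.0) == pytest.approx(100.0)

    def test_annuity_factor_at_3_percent(self):
        assert annualize(1000.0, 10, 0.03) == pytest.approx(117.23,
                                                            abs=0.01)

    def test_one_year_lifespan_scales_by_one_plus_r(self):
        r = 0.03
        assert annualize(1000.0, 1, r) == pytest.approx(1000.0 * (1 + r))

    def test_invalid_lifespan_rejected(self):
        with pytest.raises(ValueError):
            annualize(100.0, 0.5, 0.03)


class TestRollout:
    def test_cumulative_active_counts_match_plan(self, schedule):
        assert schedule.cumulative_active() == [15, 45, 84, 112, 143, 170]

    def test_grand_total_covers_78_7_percent_of_districts(self, schedule):
        assert len(schedule.entries) == 170
        assert round(districts_covered_percent(schedule), 1) == 78.7

    def test_implementation_district_years_from_staggering(self, schedule):
        # 45 districts x 9 years + 67 x 8 + 58 x 7
        assert schedule.implementation_district_years(10) == 1347

    def test_empty_plan_gives_empty_schedule(self, registry):
        plan = {r: (0,) * 6 for r in registry["region"].unique()}
        sched = expand_rollout(plan, registry)
        assert sched.entries == ()

    def test_plan_exceeding_registry_rejected(self, registry):
        plan = {"Ashanti": (100, 0, 0, 0, 0, 0)}
        with pytest.raises(ValueError):
            expand_rollout(plan, registry)


class TestCostStream:
    def test_conservation_against_per_district_rates(self, registry,
                                                     schedule):
        # with unit scaling (anchor-identical districts) the stream total
        # equals rates x district counts exactly
        flat = synth.generate_districts(170, seed=0, pop_sigma=0,
                                        stochastic_counts=False)
        sched = expand_rollout(None, flat)
        stream = compute_cost_stream(REFERENCE_COST_ITEMS, sched, flat)
        rates = per_district_annual_rates(REFERENCE_COST_ITEMS)
        expected = (170 * (rates["development"] + rates["start-up"])
                    + 1347 * rates["implementation"])
        assert stream["usd_2014"].sum() == pytest.approx(expected, abs=1.0)

    def test_one_time_phases_only_in_first_active_year(self, registry,
                                                       schedule):
        stream = compute_cost_stream(REFERENCE_COST_ITEMS, schedule,
                                     registry)
        start = dict(schedule.start_years())
        onetime = stream[stream["phase"] != "implementation"]
        for did, grp in onetime.groupby("district_id"):
            assert set(grp["year"]) == {start[did]}

    def test_adding_district_never_decreases_any_year_total(self, registry):
        base_plan = {"Ashanti": (2, 0, 0, 0, 0, 0)}
        more_plan = {"Ashanti": (2, 0, 0, 1, 0, 0)}
        s1 = expand_rollout(base_plan, registry)
        s2 = expand_rollout(more_plan, registry)
        a = compute_cost_stream(REFERENCE_COST_ITEMS, s1, registry)
        b = compute_cost_stream(REFERENCE_COST_ITEMS, s2, registry)
        ya = a.groupby("year")["usd_2014"].sum()
        yb = b.groupby("year")["usd_2014"].sum()
        ya, yb = ya.align(yb, fill_value=0.0)
        assert (yb >= ya - 1e-9).all()

    def test_scale_equivariance_doubling_amounts(self, registry, schedule):
        from dataclasses import replace
        doubled = [replace(i, amount_2014usd=2 * i.amount_2014usd)
                   for i in REFERENCE_COST_ITEMS]
        a = compute_cost_stream(REFERENCE_COST_ITEMS, schedule, registry)
        b = compute_cost_stream(doubled, schedule, registry)
        merged = a.merge(b, on=["district_id", "year", "phase"])
        assert np.allclose(merged["usd_2014_y"], 2 * merged["usd_2014_x"])

    def test_empty_schedule_gives_empty_stream(self, registry):
        stream = compute_cost_stream(REFERENCE_COST_ITEMS,
                                     RolloutSchedule(()), registry)
        assert stream["usd_2014"].sum() == 0.0


class TestSubtotalsAndShares:
    def test_implementation_items_sum_to_reference_subtotal(self):
        assert phase_subtotals(REFERENCE_COST_ITEMS)[
            "implementation"] == 24_135_461

    def test_per_district_rates_reproduce_reference_rows(self):
        rates = per_district_annual_rates(REFERENCE_COST_ITEMS)
        assert round(rates["development"]) == 4_110
        assert round(rates["start-up"]) == 44_138
        assert round(rates["implementation"]) == 17_918
        assert round(rates["total"]) == 66_166

    def test_ten_year_total_about_32_million(self):
        total = sum(phase_subtotals(REFERENCE_COST_ITEMS).values())
        assert total == pytest.approx(32.3e6, rel=0.01)

    def test_implementation_personnel_share(self):
        shares = phase_shares(REFERENCE_COST_ITEMS)
        s = shares[("implementation", "Personnel & benefits")]
        assert s == pytest.approx(11_218_454 / 24_135_461)

    def test_startup_equipment_plus_training_over_65_percent(self):
        shares = phase_shares(REFERENCE_COST_ITEMS)
        s = (shares[("start-up", "Equipment")]
             + shares[("start-up", "Training")])
        assert s >= 0.65

    def test_development_personnel_share_85_percent(self):
        shares = phase_shares(REFERENCE_COST_ITEMS)
        assert round(100 * shares[("development", "Personnel")]) == 85

    def test_single_item_phase_is_100_percent(self):
        from motech_cea.reference import CostItem
        items = [CostItem("Only", "development", "central", 10.0,
                          "lump_total")]
        assert phase_shares(items)[("development", "Only")] == 1.0

    def test_empty_phase_subtotal_flagged(self):
        from motech_cea.reference import CostItem
        items = [CostItem("Zero", "development", "central", 0.0,
                          "lump_total")]
        with pytest.raises(ValueError):
            phase_shares(items)
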