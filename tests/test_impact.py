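"""Lives-saved engine and DALY computation."""

import numpy as np
import pandas as pd
import pytest

from motech_cea import synth
from motech_cea.coverage import build_coverage_table
from motech_cea.impact import (
    EffectivenessMatrix,
    aggregate_impact,
    averted_fraction,
    calibrate_effectiveness,
    deaths_averted,
    mortality_envelope,
    yll,
    yll_per_death,
)
from motech_cea.reference import (
    DemographicParams,
    REFERENCE_LIVES_SAVED_ANCHORS,
)


class TestAvertedFraction:
    def test_zero_coverage_change_averts_nothing(self):
        assert averted_fraction(40.0, 40.0, 0.5, 0.8) == 0.0

    def test_full_protection_limit(self):
        # efficacy 1, affected 1, coverage 0 -> 100 averts everything
        assert averted_fraction(0.0, 100.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_hand_arithmetic_with_residual_mortality_denominator(self):
        # 1000 deaths x 0.8 x 0.5 x 0.20 / (1 - 0.5 x 0.20) = 88.9
        frac = averted_fraction(20.0, 40.0, 0.5, 0.8)
        assert 1000 * frac == pytest.approx(88.9, abs=0.05)

    def test_saturated_baseline_rejected(self):
        with pytest.raises(ValueError):
            averted_fraction(100.0, 100.0, 1.0, 1.0)

    def test_monotone_in_efficacy(self):
        fr = [averted_fraction(20.0, 40.0, e, 0.8)
              for e in np.linspace(0.05, 0.95, 10)]
        assert all(b > a for a, b in zip(fr, fr[1:]))


class TestYLL:
    def test_undiscounted_limit(self):
        assert yll(10.0, 65.5, 0.0) == pytest.approx(655.0)

    def test_discounted_years_per_death(self):
        assert yll(1.0, 65.5, 0.03) == pytest.approx(28.66, abs=0.01)

    def test_zero_deaths_zero_years(self):
        assert yll(0.0, 65.5, 0.03) == 0.0

    def test_maternal_remaining_years_smaller(self):
        params = DemographicParams()
        per = yll_per_death(params)
        assert 0 < per["maternal"] < per["child"] <= 65.5

    def test_stillbirth_dalys_can_be_excluded(self):
        params = DemographicParams(include_stillbirth_dalys=False)
        assert yll_per_death(params)["stillbirth"] == 0.0


@pytest.fixture(scope="module")
def small_setup():
    from motech_cea.costing import expand_rollout
    from motech_cea.reference import (
        REFERENCE_BASELINE_COVERAGE,
        REFERENCE_EFFECTS,
    )
    registry = synth.generate_districts(170, seed=7)
    schedule = expand_rollout(None, registry)
    cov = build_coverage_table(schedule, effects=REFERENCE_EFFECTS)
    params = DemographicParams()
    return registry, schedule, cov, params, dict(
        REFERENCE_BASELINE_COVERAGE)


class TestEngine:
    def test_envelope_scales_with_births(self, small_setup):
        registry, _, _, params, _ = small_setup
        env = mortality_envelope(registry, params)
        assert (env["maternal"] < env["live_births"]).all()
        np.testing.assert_allclose(
            env["child"], env["live_births"] * params.under5_mortality
            / 1000.0)

    def test_zero_coverage_gain_contributes_zero(self, small_setup):
        registry, schedule, _, params, baselines = small_setup
        cov0 = build_coverage_table(schedule, effects={})
        out = deaths_averted(registry, cov0, EffectivenessMatrix(),
                             params, baselines)
        assert out["deaths_averted"].sum() == 0.0

    def test_additive_across_districts(self, small_setup):
        registry, _, cov, params, baselines = small_setup
        eff = EffectivenessMatrix()
        full = deaths_averted(registry, cov, eff, params, baselines)
        half_ids = set(registry["district_id"][:85])
        a = deaths_averted(registry, cov[cov.district_id.isin(half_ids)],
                           eff, params, baselines)
        b = deaths_averted(registry, cov[~cov.district_id.isin(half_ids)],
                           eff, params, baselines)
        assert (a["deaths_averted"].sum() + b["deaths_averted"].sum()
                == pytest.approx(full["deaths_averted"].sum()))

    def test_unknown_district_in_coverage_rejected(self, small_setup):
        registry, _, cov, params, baselines = small_setup
        bad = cov.copy()
        bad.loc[bad.index[:3], "district_id"] = "NOPE"
        with pytest.raises(ValueError):
            deaths_averted(registry, bad, EffectivenessMatrix(), params,
                           baselines)

    def test_calibration_hits_anchor_totals_exactly(self, small_setup):
        registry, _, cov, params, baselines = small_setup
        eff = calibrate_effectiveness(
            registry, cov, EffectivenessMatrix(), params, baselines,
            REFERENCE_LIVES_SAVED_ANCHORS)
        out = deaths_averted(registry, cov, eff, params, baselines)
        totals = out.groupby("outcome")["deaths_averted"].sum()
        for oc, target in REFERENCE_LIVES_SAVED_ANCHORS.items():
            assert totals[oc] == pytest.approx(target, rel=1e-9)

    def test_calibrated_dalys_per_life_saved_in_plausible_band(
            self, small_setup):
        registry, _, cov, params, baselines = small_setup
        eff = calibrate_effectiveness(
            registry, cov, EffectivenessMatrix(), params, baselines,
            REFERENCE_LIVES_SAVED_ANCHORS)
        out = deaths_averted(registry, cov, eff, params, baselines)
        result = aggregate_impact(out, params)
        ratio = result.total_dalys() / result.total_lives_saved()
        assert 22.0 <= ratio <= 29.0


class TestAggregate:
    def test_single_district_single_year_equals_district_result(self):
        per = pd.DataFrame({
            "district_id": ["D001"], "year": [2], "outcome": ["child"],
            "deaths_averted": [12.5]})
        res = aggregate_impact(per, DemographicParams(), horizon_years=3)
        assert res.total_lives_saved() == 12.5
        assert res.dalys.loc[2] == pytest.approx(12.5 * 28.6615, abs=0.01)
        assert res.dalys.loc[1] == 0.0

    def test_year2_component_sum_and_child_share(self):
        # aggregation over the reference Year-2 components
        from motech_cea.reference import REFERENCE_YEAR2_COMPONENTS
        per = pd.DataFrame({
            "district_id": "NATIONAL",
            "year": 2,
            "outcome": list(REFERENCE_YEAR2_COMPONENTS),
            "deaths_averted": list(REFERENCE_YEAR2_COMPONENTS.values()),
        })
        res = aggregate_impact(per, DemographicParams(), horizon_years=2)
        assert res.total_lives_saved() == 483
        child = res.totals_by_outcome()["child"]
        assert round(100 * child / res.total_lives_saved(), 1) == 59.6

    def test_zero_deaths_zero_dalys_invariant(self):
        per = pd.DataFrame({"district_id": [], "year": [], "outcome": [],
                            "deaths_averted": []})
        res = aggregate_impact(per, DemographicParams(), horizon_years=5)
        assert res.total_dalys() == 0.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            aggregate_impact(pd.DataFrame({"year": [1]}),
                             DemographicParams())
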