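"""Tornado, Monte Carlo PSA, CEAC and CE plane."""

import numpy as np
import pandas as pd
import pytest

from motech_cea.impact import EffectivenessMatrix, calibrate_effectiveness
from motech_cea.coverage import build_coverage_table
from motech_cea.reference import (
    DemographicParams,
    REFERENCE_BASELINE_COVERAGE,
    REFERENCE_COST_ITEMS,
    REFERENCE_EFFECTS,
    REFERENCE_LIVES_SAVED_ANCHORS,
)
from motech_cea.uncertainty import (
    CEModel,
    ParameterSpec,
    ce_plane,
    ceac,
    default_parameter_specs,
    one_way,
    psa_summary,
    run_psa,
)


@pytest.fixture(scope="module")
def model(registry, schedule):
    params = DemographicParams()
    cov = build_coverage_table(schedule, effects=REFERENCE_EFFECTS)
    eff = calibrate_effectiveness(
        registry, cov, EffectivenessMatrix(), params,
        REFERENCE_BASELINE_COVERAGE, REFERENCE_LIVES_SAVED_ANCHORS)
    return CEModel(registry, schedule, REFERENCE_COST_ITEMS, eff, params,
                   REFERENCE_BASELINE_COVERAGE, dict(REFERENCE_EFFECTS))


@pytest.fixture(scope="module")
def specs():
    return default_parameter_specs(REFERENCE_COST_ITEMS,
                                   dict(REFERENCE_EFFECTS))


class TestModelClosure:
    def test_matches_full_pipeline_computation(self, model, registry,
                                               schedule):
        # the fast closure must agree with the stage-by-stage route
        from motech_cea.costing import compute_cost_stream
        from motech_cea.impact import aggregate_impact, deaths_averted
        params = DemographicParams()
        cov = build_coverage_table(schedule, effects=REFERENCE_EFFECTS)
        stream = compute_cost_stream(REFERENCE_COST_ITEMS, schedule,
                                     registry)
        per = deaths_averted(registry, cov, model.eff, params,
                             REFERENCE_BASELINE_COVERAGE)
        agg = aggregate_impact(per, params)
        cost, dalys, deaths = model.evaluate()
        assert cost == pytest.approx(stream["usd_2014"].sum(), rel=1e-9)
        assert dalys == pytest.approx(agg.total_dalys(), rel=1e-9)
        assert deaths == pytest.approx(agg.total_lives_saved(), rel=1e-9)

    def test_calibrated_deaths_match_anchors(self, model):
        _, _, deaths = model.evaluate()
        assert deaths == pytest.approx(
            sum(REFERENCE_LIVES_SAVED_ANCHORS.values()), rel=1e-9)


class TestOneWay:
    def test_ignored_parameter_has_zero_span_and_ranks_last(self, model):
        specs = [
            ParameterSpec("effect_sba", 11.0, low=8.8, high=13.2),
            ParameterSpec("not_in_model", 1.0, low=0.8, high=1.2),
        ]
        df = one_way(model, specs)
        assert df.iloc[-1]["name"] == "not_in_model"
        assert df.iloc[-1]["span"] == 0.0

    def test_effect_parameters_rank_above_most_cost_items(self, model,
                                                          specs):
        df = one_way(model, specs)
        top = df.iloc[0]["name"]
        assert top.startswith(("lives_", "effect_"))
        # implementation personnel is the highest-ranked cost item
        cost_rows = df[df["name"].str.startswith("cost:")]
        assert (cost_rows.iloc[0]["name"]
                == "cost:implementation:Personnel & benefits")

    def test_identical_spans_ordered_alphabetically(self, model):
        specs = [
            ParameterSpec("zzz_unused", 1.0, low=0.8, high=1.2),
            ParameterSpec("aaa_unused", 1.0, low=0.8, high=1.2),
        ]
        df = one_way(model, specs)
        assert list(df["name"]) == ["aaa_unused", "zzz_unused"]

    def test_ordering_invariant_to_spec_listing_order(self, model, specs):
        a = one_way(model, specs)
        b = one_way(model, list(reversed(specs)))
        assert list(a["name"]) == list(b["name"])


class TestPSA:
    def test_all_fixed_distributions_reproduce_deterministic_run(
            self, model, specs):
        fixed = [ParameterSpec(s.name, s.base, "fixed", {},
                               s.low, s.high, s.domain) for s in specs]
        draws = run_psa(model, fixed, n_iter=5, seed=0)
        cost, dalys, _ = model.evaluate()
        assert np.allclose(draws["incremental_cost"], cost)
        assert np.allclose(draws["dalys_averted"], dalys)
        assert psa_summary(draws)["icer_mean"] == pytest.approx(
            cost / dalys)

    def test_fixed_seed_reproduces_draw_table(self, model, specs, tmp_path):
        a = run_psa(model, specs, n_iter=50, seed=3)
        b = run_psa(model, specs, n_iter=50, seed=3)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_symmetric_cost_draws_unbiased_mean(self, model):
        # cost-only sampling at 10% normal spread: the PSA mean cost
        # stays within 1% of the deterministic cost over 20 seeds
        det_cost, _, _ = model.evaluate()
        specs = [
            ParameterSpec(f"cost:{i.phase}:{i.activity}", i.amount_2014usd,
                          "normal", {"sd": 0.10 * i.amount_2014usd},
                          domain=(0.0, np.inf))
            for i in REFERENCE_COST_ITEMS if i.amount_2014usd > 0
        ]
        rel_err = []
        for seed in range(20):
            draws = run_psa(model, specs, n_iter=200, seed=seed)
            rel_err.append(abs(draws["incremental_cost"].mean()
                               - det_cost) / det_cost)
        assert np.mean(rel_err) < 0.01


class TestCEAC:
    def test_hand_draw_nmb_count(self):
        draws = pd.DataFrame({
            "incremental_cost": [10, 10, 30, 5, 50],
            "dalys_averted": [1, 2, 1, 1, 1],
        })
        curve = ceac(draws, (10.0,))
        assert curve["probability"].iloc[0] == pytest.approx(0.6)

    def test_zero_wtp_with_positive_costs_probability_zero(self):
        draws = pd.DataFrame({"incremental_cost": [5.0, 2.0],
                              "dalys_averted": [1.0, 1.0]})
        assert ceac(draws, (0.0,))["probability"].iloc[0] == 0.0

    def test_huge_wtp_with_positive_dalys_probability_one(self):
        draws = pd.DataFrame({"incremental_cost": [5.0, 2.0],
                              "dalys_averted": [1.0, 0.5]})
        assert ceac(draws, (1e12,))["probability"].iloc[0] == 1.0

    def test_curve_non_decreasing_in_wtp(self, model, specs):
        draws = run_psa(model, specs, n_iter=100, seed=1)
        grid = tuple(np.linspace(0, 100, 41))
        curve = ceac(draws, grid)
        p = curve["probability"].to_numpy()
        assert (np.diff(p) >= 0).all()

    def test_empty_grid_rejected(self):
        draws = pd.DataFrame({"incremental_cost": [1.0],
                              "dalys_averted": [1.0]})
        with pytest.raises(ValueError):
            ceac(draws, ())


class TestCEPlane:
    def test_all_positive_draws_fall_northeast(self, model, specs):
        draws = run_psa(model, specs, n_iter=100, seed=2)
        q = ce_plane(draws)
        assert q["northeast"] == 100
        assert q["southeast"] == q["northwest"] == q["southwest"] == 0

    def test_single_negative_cost_draw_goes_south(self):
        draws = pd.DataFrame({"incremental_cost": [-1.0],
                              "dalys_averted": [1.0]})
        assert ce_plane(draws)["southeast"] == 1

    def test_symmetric_zero_mean_draws_quarter_each(self):
        rng = np.random.default_rng(0)
        draws = pd.DataFrame({
            "incremental_cost": rng.normal(size=10_000),
            "dalys_averted": rng.normal(size=10_000),
        })
        q = ce_plane(draws)
        for v in q.values():
            assert abs(v / 10_000 - 0.25) < 0.02
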