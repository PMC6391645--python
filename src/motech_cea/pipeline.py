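"""Config-driven end-to-end runner.

Stages hand off through flat files (CSV + JSON) in the run directory so
every intermediate is auditable and any stage can be re-run from its
persisted inputs: synthesis -> effect estimation -> costing -> coverage ->
impact -> cea -> uncertainty.  A manifest records the config hash, seed,
package version and a SHA-256 checksum of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .reference import (
    DemographicParams,
    GNI_PER_CAPITA_USD,
    HORIZON_YEARS,
    RAMP_YEARS,
    REFERENCE_BASELINE_COVERAGE,
    REFERENCE_COST_ITEMS,
    REFERENCE_EFFECTS,
    REFERENCE_LIVES_SAVED_ANCHORS,
    DEFAULT_WTP_GRID,
)
from . import cea as cea_mod
from . import costing, coverage, effects as effects_mod, impact as impact_mod
from . import synth, uncertainty

log = logging.getLogger("motech_cea")

STAGES = ("synth", "effects", "costs", "coverage", "impact", "cea",
          "uncertainty")


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_districts: int = 170
    n_per_arm: int = 5000
    horizon_years: int = HORIZON_YEARS
    ramp_years: int = RAMP_YEARS
    discount_rate: float = 0.03
    caliper: float = Field(default=float("inf"))
    n_boot: int = 500
    # "estimated": carry the matched ATT estimates into coverage;
    # "reference": carry the published 11/10/6 point effects.
    effects_source: Literal["estimated", "reference"] = "estimated"
    calibrate: bool = True
    lives_saved_anchors: dict[str, float] = Field(
        default_factory=lambda: dict(REFERENCE_LIVES_SAVED_ANCHORS))
    baseline_coverage: dict[str, float] = Field(
        default_factory=lambda: dict(REFERENCE_BASELINE_COVERAGE))
    demographics: dict[str, float | bool] = Field(default_factory=dict)
    n_psa_iterations: int = 1000
    wtp_grid: list[float] = Field(
        default_factory=lambda: list(DEFAULT_WTP_GRID))
    per_capita_income: float = GNI_PER_CAPITA_USD
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    make_figures: bool = True

    def demographic_params(self) -> DemographicParams:
        return DemographicParams(**self.demographics)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML or JSON config file, then apply keyword overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# --------------------------------------------------------------------------
# Stages (each reads persisted inputs from outdir, writes outputs there)
# --------------------------------------------------------------------------

def stage_synth(config: RunConfig, outdir: Path) -> dict[str, Path]:
    paths = synth.write_inputs(
        outdir, n_districts=config.n_districts, n_per_arm=config.n_per_arm,
        seed=config.seed)
    return {k: p for k, p in paths.items()}


def stage_effects(config: RunConfig, outdir: Path) -> dict[str, Path]:
    records = pd.read_csv(outdir / "exit_interviews.csv")
    estimates = effects_mod.estimate_all_effects(
        records, caliper=config.caliper, n_boot=config.n_boot,
        seed=config.seed)
    path = effects_mod.write_effects(estimates, outdir / "effects.json")
    return {"effects": path}


def _load_effect_points(config: RunConfig, outdir: Path) -> dict[str, float]:
    if config.effects_source == "reference":
        return dict(REFERENCE_EFFECTS)
    payload = json.loads((outdir / "effects.json").read_text())
    # coverage decline is not modelled: non-positive estimates carry no gain
    return {k: max(0.0, 100.0 * v["att"]) for k, v in payload.items()}


def stage_costs(config: RunConfig, outdir: Path) -> dict[str, Path]:
    registry = pd.read_csv(outdir / "districts.csv")
    schedule = costing.expand_rollout(None, registry)
    stream = costing.compute_cost_stream(
        REFERENCE_COST_ITEMS, schedule, registry,
        horizon_years=config.horizon_years,
        discount_rate=config.discount_rate)
    paths = costing.write_cost_outputs(stream, REFERENCE_COST_ITEMS, outdir)
    sched_path = outdir / "rollout_schedule.csv"
    pd.DataFrame(schedule.entries,
                 columns=["district_id", "start_period"]
                 ).to_csv(sched_path, index=False)
    paths["rollout_schedule"] = sched_path
    return paths


def _load_schedule(outdir: Path) -> costing.RolloutSchedule:
    df = pd.read_csv(outdir / "rollout_schedule.csv")
    return costing.RolloutSchedule(
        tuple(sorted((r.district_id, int(r.start_period))
                     for r in df.itertuples())))


def stage_coverage(config: RunConfig, outdir: Path) -> dict[str, Path]:
    schedule = _load_schedule(outdir)
    points = _load_effect_points(config, outdir)
    table = coverage.build_coverage_table(
        schedule, effects=points, baselines=config.baseline_coverage,
        horizon_years=config.horizon_years, ramp_years=config.ramp_years)
    return {"coverage": coverage.write_coverage(table, outdir)}


def _calibrated_matrix(config: RunConfig, registry: pd.DataFrame,
                       cov_table: pd.DataFrame,
                       params: DemographicParams
                       ) -> impact_mod.EffectivenessMatrix:
    eff = impact_mod.EffectivenessMatrix()
    if config.calibrate:
        eff = impact_mod.calibrate_effectiveness(
            registry, cov_table, eff, params, config.baseline_coverage,
            config.lives_saved_anchors)
    return eff


def stage_impact(config: RunConfig, outdir: Path) -> dict[str, Path]:
    registry = pd.read_csv(outdir / "districts.csv")
    cov_table = pd.read_csv(outdir / "coverage.csv")
    params = config.demographic_params()
    eff = _calibrated_matrix(config, registry, cov_table, params)
    per_district = impact_mod.deaths_averted(
        registry, cov_table, eff, params, config.baseline_coverage)
    result = impact_mod.aggregate_impact(per_district, params,
                                         config.horizon_years)
    return impact_mod.write_impact(result, outdir)


def stage_cea(config: RunConfig, outdir: Path) -> dict[str, Path]:
    stream = pd.read_csv(outdir / "cost_stream.csv")
    table = pd.read_csv(outdir / "impact.csv")
    params = config.demographic_params()
    per_year = table.groupby(["year", "outcome"], as_index=False)[
        ["deaths_averted", "dalys"]].sum()
    result = impact_mod.ImpactResult(
        deaths_averted=per_year[["year", "outcome", "deaths_averted"]],
        dalys=per_year.groupby("year")["dalys"].sum().reindex(
            range(1, config.horizon_years + 1), fill_value=0.0),
        params=params)
    records = cea_mod.icer_table(stream, result, config.horizon_years)
    path = cea_mod.write_icers(records, outdir,
                               per_capita_income=config.per_capita_income)
    return {"icers": path}


def stage_uncertainty(config: RunConfig, outdir: Path) -> dict[str, Path]:
    registry = pd.read_csv(outdir / "districts.csv")
    cov_table = pd.read_csv(outdir / "coverage.csv")
    schedule = _load_schedule(outdir)
    params = config.demographic_params()
    points = _load_effect_points(config, outdir)
    eff = _calibrated_matrix(config, registry, cov_table, params)
    model = uncertainty.CEModel(
        registry, schedule, REFERENCE_COST_ITEMS, eff, params,
        config.baseline_coverage, points,
        horizon_years=config.horizon_years, ramp_years=config.ramp_years)
    specs = uncertainty.default_parameter_specs(
        REFERENCE_COST_ITEMS, points)

    tornado = uncertainty.one_way(model, specs)
    draws = uncertainty.run_psa(model, specs,
                                n_iter=config.n_psa_iterations,
                                seed=config.seed)
    curve = uncertainty.ceac(draws, tuple(config.wtp_grid))
    quadrants = uncertainty.ce_plane(draws)
    summary = uncertainty.psa_summary(draws)
    summary["quadrants"] = quadrants

    paths: dict[str, Path] = {}
    paths["tornado"] = outdir / "tornado.csv"
    tornado.to_csv(paths["tornado"], index=False)
    paths["psa_draws"] = outdir / "psa_draws.csv"
    draws.to_csv(paths["psa_draws"], index=False)
    paths["ceac"] = outdir / "ceac.csv"
    curve.to_csv(paths["ceac"], index=False)
    paths["psa_summary"] = outdir / "psa_summary.json"
    paths["psa_summary"].write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    if config.make_figures:
        paths["ce_plane_fig"] = uncertainty.plot_ce_plane(
            draws, outdir / "ce_plane.svg")
        paths["ceac_fig"] = uncertainty.plot_ceac(
            curve, outdir / "ceac.svg")
        paths["tornado_fig"] = uncertainty.plot_tornado(
            tornado, model.icer(), outdir / "tornado.svg")
    return paths


_STAGE_FUNCS = {
    "synth": stage_synth,
    "effects": stage_effects,
    "costs": stage_costs,
    "coverage": stage_coverage,
    "impact": stage_impact,
    "cea": stage_cea,
    "uncertainty": stage_uncertainty,
}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            paths = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            name: {"file": p.name, "sha256": _sha256(p)}
            for name, p in paths.items()
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
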