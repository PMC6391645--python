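"""Synthetic input generation.

The analysis consumes two field datasets that cannot be redistributed: the
2010 census-derived district registry (population and facility counts for
each district) and endline exit-interview records from the Gomoa West
evaluation.  This module generates statistically analogous stand-ins:

* :func:`generate_districts` draws a registry whose expected
  population-per-CHPS and population-per-health-center ratios match the
  Gomoa West anchor district, with log-normally distributed populations;
* :func:`generate_exit_interviews` draws client interview records with a
  *known* embedded treatment effect on each service-use outcome and, when
  confounding is enabled, covariates that influence both program exposure
  and outcomes — so a naive treated-minus-control comparison is biased but
  the true effect on the treated is recoverable by matching.

Both generators are deterministic given their seed; inputs and the seed
are recorded in a sidecar JSON manifest by :func:`write_inputs`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import (
    DEFAULT_CRUDE_BIRTH_RATE,
    District,
    GOMOA_WEST,
    INTERVENTIONS,
    REFERENCE_CPI,
    REFERENCE_FX,
    REGION_TOTALS,
    REGIONS,
)

DISTRICT_COLUMNS = ["district_id", "region", "population", "n_chps",
                    "n_health_centers", "n_hospitals", "n_nurses",
                    "crude_birth_rate"]

#: Baseline probability of each service-use outcome in the control arm.
DEFAULT_OUTCOME_BASELINES = {
    "sba": 0.70,
    "facility_delivery": 0.57,
    "measles": 0.88,
}

#: Strength with which the shared covariate index shifts each outcome
#: probability (scaled by the ``confounding`` knob).
DEFAULT_CONFOUNDING_SLOPES = {
    "sba": 0.15,
    "facility_delivery": 0.15,
    "measles": 0.045,
}


def _allocate_regions(n: int) -> list[str]:
    """Split n districts across the 10 regions, largest-remainder on the
    planned regional totals (so n=170 reproduces the plan exactly)."""
    total = sum(REGION_TOTALS.values())
    quotas = {r: n * REGION_TOTALS[r] / total for r in REGIONS}
    counts = {r: int(np.floor(quotas[r])) for r in REGIONS}
    short = n - sum(counts.values())
    for r in sorted(REGIONS, key=lambda r: quotas[r] - counts[r],
                    reverse=True)[:short]:
        counts[r] += 1
    out: list[str] = []
    for r in REGIONS:
        out.extend([r] * counts[r])
    return out


def generate_districts(
    n: int,
    seed: int,
    anchor: District = GOMOA_WEST,
    pop_sigma: float = 0.35,
    stochastic_counts: bool = True,
    nurses_per_facility: float = 2.0,
    crude_birth_rate: float | None = None,
) -> pd.DataFrame:
    """Generate a district registry anchored to Gomoa West's ratios.

    Populations are log-normal with mean equal to the anchor population
    (``pop_sigma`` is the log-scale SD; 0 gives every district the anchor
    population).  Facility counts are Poisson with expectation
    population/ratio, so the expected population-per-facility ratios match
    the anchor; with ``stochastic_counts=False`` they are deterministic
    rounded expectations, and ``n=1`` with ``pop_sigma=0`` reproduces the
    anchor district exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cbr = (anchor.crude_birth_rate if crude_birth_rate is None
           else crude_birth_rate)

    if pop_sigma == 0:
        pop = np.full(n, float(anchor.population))
    else:
        mu = np.log(anchor.population) - 0.5 * pop_sigma ** 2
        pop = rng.lognormal(mean=mu, sigma=pop_sigma, size=n)
    pop = np.maximum(1, np.round(pop)).astype(int)

    chps_ratio = anchor.population / anchor.n_chps
    hc_ratio = anchor.population / anchor.n_health_centers
    hosp_ratio = (anchor.population / anchor.n_hospitals
                  if anchor.n_hospitals else np.inf)

    def counts(expected: np.ndarray) -> np.ndarray:
        if stochastic_counts:
            return rng.poisson(expected)
        return np.round(expected).astype(int)

    n_chps = np.maximum(1, counts(pop / chps_ratio))
    n_hc = counts(pop / hc_ratio)
    n_hosp = (counts(pop / hosp_ratio) if np.isfinite(hosp_ratio)
              else np.zeros(n, dtype=int))
    expected_nurses = nurses_per_facility * (n_chps + n_hc)
    n_nurses = np.maximum(1, counts(expected_nurses.astype(float)))

    df = pd.DataFrame({
        "district_id": [f"D{i + 1:03d}" for i in range(n)],
        "region": _allocate_regions(n),
        "population": pop,
        "n_chps": n_chps.astype(int),
        "n_health_centers": n_hc.astype(int),
        "n_hospitals": n_hosp.astype(int),
        "n_nurses": n_nurses.astype(int),
        "crude_birth_rate": float(cbr),
    })
    return df[DISTRICT_COLUMNS]


# --------------------------------------------------------------------------
# Exit interviews
# --------------------------------------------------------------------------

# Covariate index weights: each component is scaled to [0, 1] before
# summing, then the sum is centred and rescaled to roughly [-1, 1].
_INDEX_CENTER = 2.496  # mean of the five rescaled components
_INDEX_SCALE = 2.5


def _covariate_index(df: pd.DataFrame) -> np.ndarray:
    raw = (df["education"] / 3.0
           + df["employment"]
           + (df["marital_status"] == "married").astype(float)
           + (df["age"] - 15) / 34.0
           + (df["income"] - 1) / 4.0)
    return ((raw - _INDEX_CENTER) / _INDEX_SCALE).to_numpy()


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "education": rng.choice(4, size=n, p=[0.30, 0.35, 0.25, 0.10]),
        "employment": rng.choice(2, size=n, p=[0.45, 0.55]),
        "marital_status": rng.choice(
            np.array(["single", "married", "other"]),
            size=n, p=[0.25, 0.65, 0.10]),
        "age": rng.integers(15, 50, size=n),
        "income": rng.choice(np.arange(1, 6), size=n,
                             p=[0.25, 0.25, 0.20, 0.20, 0.10]),
    })


def generate_exit_interviews(
    n_per_arm: int,
    true_effects: dict[str, float],
    seed: int,
    baselines: dict[str, float] | None = None,
    confounding: float = 1.0,
    treatment_slope: float = 2.0,
) -> pd.DataFrame:
    """Generate exit-interview records with an embedded treatment effect.

    Outcomes follow an additive probability model
    ``p = baseline + slope * confounding * z + effect * treated`` where
    ``z`` is a shared index of the five covariates (education, employment,
    marital status, age, income).  The same index tilts treatment
    assignment (strength ``treatment_slope * confounding``), so with
    confounding on the naive arm difference over-states the true effect on
    the treated, which equals ``true_effects`` exactly by construction.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    baselines = dict(DEFAULT_OUTCOME_BASELINES if baselines is None
                     else baselines)
    for name in true_effects:
        if name not in baselines:
            raise ValueError(f"no baseline for outcome {name!r}")
        p_max = baselines[name] + true_effects[name]
        if not 0.0 <= p_max <= 1.0 or not 0.0 <= baselines[name] <= 1.0:
            raise ValueError(
                f"baseline + effect for {name!r} outside [0, 1]")

    rng = np.random.default_rng(seed)
    # Oversample a pool, assign treatment, then take the first n of each
    # arm; keeps the covariate-treatment dependence while hitting the
    # requested arm sizes exactly.
    pool = max(4 * n_per_arm, 200)
    df = _draw_covariates(rng, pool)
    z = _covariate_index(df)
    p_treat = 1.0 / (1.0 + np.exp(-(treatment_slope * confounding) * z))
    treated = rng.random(pool) < p_treat
    idx_t = np.flatnonzero(treated)[:n_per_arm]
    idx_c = np.flatnonzero(~treated)[:n_per_arm]
    if len(idx_t) < n_per_arm or len(idx_c) < n_per_arm:  # pragma: no cover
        raise RuntimeError("oversampling pool exhausted; increase pool")
    keep = np.sort(np.concatenate([idx_t, idx_c]))
    df = df.iloc[keep].reset_index(drop=True)
    z = z[keep]
    t = treated[keep].astype(int)

    out = df.copy()
    out.insert(0, "record_id",
               [f"R{i + 1:06d}" for i in range(len(out))])
    out.insert(1, "treated", t)
    for name in INTERVENTIONS:
        base = baselines.get(name)
        if base is None:
            continue
        eff = float(true_effects.get(name, 0.0))
        slope = DEFAULT_CONFOUNDING_SLOPES.get(name, 0.08)
        p = np.clip(base + slope * confounding * z + eff * t, 0.005, 0.995)
        out[f"outcome_{name}"] = (rng.random(len(out)) < p).astype(int)
    return out


# --------------------------------------------------------------------------
# File interface
# --------------------------------------------------------------------------

def fx_table() -> pd.DataFrame:
    """Month-by-month local-currency-per-USD rates as a two-column table."""
    return pd.DataFrame(sorted(REFERENCE_FX.items()),
                        columns=["month", "ghs_per_usd"])


def cpi_table() -> pd.DataFrame:
    """Annual CPI with 2014 as the base year."""
    return pd.DataFrame(sorted(REFERENCE_CPI.items()),
                        columns=["year", "cpi"])


def write_inputs(
    outdir: str | Path,
    n_districts: int = 170,
    n_per_arm: int = 5000,
    true_effects: dict[str, float] | None = None,
    seed: int = 0,
    **district_kwargs,
) -> dict[str, Path]:
    """Generate and write every pipeline input under ``outdir``.

    Writes districts.csv, exit_interviews.csv, fx.csv, cpi.csv plus a
    synthesis_manifest.json recording the generator parameters and seed.
    """
    from .reference import REFERENCE_EFFECTS

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    effects = ({k: v / 100.0 for k, v in REFERENCE_EFFECTS.items()}
               if true_effects is None else dict(true_effects))

    districts = generate_districts(n_districts, seed=seed, **district_kwargs)
    interviews = generate_exit_interviews(n_per_arm, effects, seed=seed + 1)

    paths = {
        "districts": outdir / "districts.csv",
        "exit_interviews": outdir / "exit_interviews.csv",
        "fx": outdir / "fx.csv",
        "cpi": outdir / "cpi.csv",
    }
    districts.to_csv(paths["districts"], index=False)
    interviews.to_csv(paths["exit_interviews"], index=False)
    fx_table().to_csv(paths["fx"], index=False)
    cpi_table().to_csv(paths["cpi"], index=False)

    manifest = {
        "seed": seed,
        "n_districts": n_districts,
        "n_per_arm": n_per_arm,
        "true_effects": effects,
        "district_kwargs": {k: repr(v) for k, v in district_kwargs.items()},
        "crude_birth_rate_default": DEFAULT_CRUDE_BIRTH_RATE,
        "files": {k: p.name for k, p in paths.items()},
    }
    mpath = outdir / "synthesis_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths
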