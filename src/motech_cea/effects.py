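"""Propensity-score estimation of program effects on service coverage.

The field evaluation compared service use between program-exposed and
comparison clients at endline.  Because exposure was not randomized at the
individual level, the effect of the program on the exposed (ATT) is
estimated by (1) fitting a logistic propensity model of exposure on five
covariates — education, employment, marital status, age, income — and
(2) matching each treated record to its nearest control by propensity
score (1:1, with replacement), the ATT being the mean treated-minus-
matched-control outcome difference.  Standard errors come from a
nonparametric bootstrap over treated records.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

SCORE_FLOOR = 1e-6
COVARIATES = ("education", "employment", "marital_status", "age", "income")


@dataclass
class PropensityFit:
    coefficients: dict[str, float]
    scores: pd.Series          # indexed by record_id, in (0, 1)
    separation: bool = False   # perfect/quasi-separation diagnostic


@dataclass
class ATTEstimate:
    outcome: str
    att: float
    n_matched_pairs: int
    se: float
    n_discarded: int = 0  # treated records with no control inside caliper


def _design_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: ordinal covariates as-is, marital status
    one-hot (reference = first category), constant-valued columns dropped."""
    X = pd.DataFrame(index=records.index)
    X["education"] = records["education"].astype(float)
    X["employment"] = records["employment"].astype(float)
    marital = pd.get_dummies(records["marital_status"], prefix="marital",
                             drop_first=True, dtype=float)
    for c in marital.columns:
        X[c] = marital[c]
    X["age"] = records["age"].astype(float)
    X["income"] = records["income"].astype(float)
    return X.loc[:, X.nunique() > 1]


def fit_propensity(records: pd.DataFrame) -> PropensityFit:
    """Fit a maximum-likelihood logistic model of treatment on covariates.

    Returns one fitted score per record, clipped away from {0, 1}.  If the
    data are (quasi-)separated the fit falls back to an L2-regularized
    solution and the ``separation`` diagnostic is set.
    """
    t = records["treated"].to_numpy(dtype=float)
    if (t == 1).sum() < 2 or (t == 0).sum() < 2:
        raise ValueError("need at least 2 records per arm")
    X = _design_matrix(records)
    if X.shape[1] == 0:
        # all covariates constant: intercept-only fit, score = treated share
        share = float(t.mean())
        scores = pd.Series(np.clip(np.full(len(records), share),
                                   SCORE_FLOOR, 1 - SCORE_FLOOR),
                           index=records["record_id"].to_numpy())
        return PropensityFit({"const": math.log(share / (1 - share))},
                             scores)

    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(t, Xc).fit(disp=False, maxiter=200)
        p = np.asarray(res.predict(Xc))
        params = res.params
        if (not np.all(np.isfinite(params))
                or np.any(p <= SCORE_FLOOR) or np.any(p >= 1 - SCORE_FLOOR)
                or not res.mle_retvals.get("converged", True)):
            separation = True
    except Exception:
        separation = True
    if separation:
        with np.errstate(all="ignore"):
            res = sm.Logit(t, Xc).fit_regularized(
                disp=False, alpha=1.0, maxiter=500)
        p = np.asarray(res.predict(Xc))
        params = res.params

    scores = pd.Series(np.clip(p, SCORE_FLOOR, 1 - SCORE_FLOOR),
                       index=records["record_id"].to_numpy())
    coefs = {name: float(v) for name, v in zip(Xc.columns, params)}
    return PropensityFit(coefs, scores, separation=separation)


def _nearest_controls(treated_scores: np.ndarray,
                      control_scores: np.ndarray,
                      control_order: np.ndarray) -> np.ndarray:
    """Index (into the control arrays) of the nearest control per treated
    score.  ``control_scores`` must be sorted ascending with ties already
    ordered by record_id, so equal-score ties resolve to the lowest id;
    equal-distance ties between a left and right neighbour resolve to the
    candidate with the lexicographically smaller record_id."""
    pos = np.searchsorted(control_scores, treated_scores, side="left")
    left = np.clip(pos - 1, 0, len(control_scores) - 1)
    right = np.clip(pos, 0, len(control_scores) - 1)
    d_left = np.abs(treated_scores - control_scores[left])
    d_right = np.abs(treated_scores - control_scores[right])
    pick_right = d_right < d_left
    tie = d_right == d_left
    if tie.any():
        # break exact distance ties by record_id
        pick_right[tie] = (control_order[right[tie]]
                           < control_order[left[tie]])
    return np.where(pick_right, right, left)


def estimate_att(
    records: pd.DataFrame,
    fit: PropensityFit,
    outcome: str,
    caliper: float = math.inf,
    n_boot: int = 500,
    seed: int = 0,
) -> ATTEstimate:
    """ATT by 1:1 nearest-neighbour matching (with replacement) on score.

    Treated records with no control inside the caliper are dropped and
    counted in ``n_discarded``.  The bootstrap resamples treated records.
    """
    col = outcome if outcome in records.columns else f"outcome_{outcome}"
    if col not in records.columns:
        raise KeyError(f"outcome column {outcome!r} not found")
    ids = records["record_id"].to_numpy()
    missing = [i for i in ids if i not in fit.scores.index]
    if missing:
        raise ValueError(f"{len(missing)} records lack propensity scores")
    scores = fit.scores.loc[ids].to_numpy()
    y = records[col].to_numpy(dtype=float)
    t = records["treated"].to_numpy(dtype=bool)

    c_ids, c_scores, c_y = ids[~t], scores[~t], y[~t]
    order = np.lexsort((c_ids, c_scores))
    c_ids, c_scores, c_y = c_ids[order], c_scores[order], c_y[order]
    # rank of each sorted control's record_id, for tie-breaks
    c_rank = np.argsort(np.argsort(c_ids, kind="stable"), kind="stable")

    t_scores, t_y = scores[t], y[t]
    match = _nearest_controls(t_scores, c_scores, c_rank)
    dist = np.abs(t_scores - c_scores[match])
    ok = dist <= caliper
    n_discarded = int((~ok).sum())
    diffs = t_y[ok] - c_y[match[ok]]
    if len(diffs) == 0:
        raise ValueError("no treated record matched within the caliper")
    att = float(diffs.mean())

    rng = np.random.default_rng(seed)
    if n_boot > 0 and len(diffs) > 1:
        idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
        se = float(diffs[idx].mean(axis=1).std(ddof=1))
    else:
        se = float("nan")
    return ATTEstimate(outcome=outcome, att=att,
                       n_matched_pairs=int(len(diffs)), se=se,
                       n_discarded=n_discarded)


def estimate_all_effects(
    records: pd.DataFrame,
    outcomes: tuple[str, ...] = ("sba", "facility_delivery", "measles"),
    caliper: float = math.inf,
    n_boot: int = 500,
    seed: int = 0,
) -> dict[str, ATTEstimate]:
    """Propensity fit plus ATT for each outcome, on one shared fit."""
    fit = fit_propensity(records)
    return {o: estimate_att(records, fit, o, caliper=caliper,
                            n_boot=n_boot, seed=seed)
            for o in outcomes}


def write_effects(estimates: dict[str, ATTEstimate],
                  path: str | Path) -> Path:
    """Persist ATT estimates as effects.json for the coverage stage."""
    path = Path(path)
    payload = {
        o: {"att": e.att, "se": e.se, "n_matched_pairs": e.n_matched_pairs,
            "n_discarded": e.n_discarded}
        for o, e in estimates.items()
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
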