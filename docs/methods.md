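# Methods

This note documents the models, parameter choices, numerical conventions
and limitations behind the package. It is written for a reader who wants
to audit or adapt the analysis; the README gives the quick tour.

## Scope and comparator

The analysis forecasts the incremental cost-effectiveness of scaling the
MOTECH program (Mobile Midwife voice messaging + the Client Data
Application for frontline nurses) to 170 of Ghana's 216 districts over a
10-year horizon, against a status-quo comparator with zero incremental
cost and effect. Costs take a program perspective in 2014 USD; health
effects are maternal deaths, under-five deaths and stillbirths averted,
valued as years-of-life-lost-only DALYs.

## Synthetic inputs

Two field datasets are replaced by generators (`motech_cea.synth`):

**District registry.** Populations are log-normal with mean equal to the
Gomoa West anchor (135,139) and log-SD 0.35 — district sizes are
right-skewed in practice and log-normality keeps all values positive.
Facility counts are Poisson with expectation population/ratio, using the
anchor ratios (1 CHPS per 7,949 people, 1 health center per 33,785), so
expected population-per-facility matches the anchor; nurse counts default
to 2 per frontline facility. The crude birth rate is a single national
constant, 33 per 1,000 — the value consistent with ~3,100 annual maternal
deaths at an MMR of 380/100,000 on 24.5 million people — so that impact
differences across districts reflect size, not demographic noise.
Regions are allocated by largest remainder on the rollout plan's regional
totals (at n=170 the plan is reproduced exactly).

**Exit interviews.** Five covariates (education 0–3, employment, marital
status, age 15–49, income bracket 1–5) feed a shared, centred linear
index z ∈ ≈[−1, 1]. Treatment assignment is logistic in z (slope 2.0)
and each binary outcome follows an additive probability model
`p = baseline + γ·z + effect·treated` (γ = 0.15 for delivery outcomes,
0.045 for measles; baselines 0.70/0.57/0.88). Because the model is
additive and clipping never binds at the default settings, the true
effect on the treated equals the embedded effect exactly, while the
naive arm contrast is biased upward by ≈3 coverage points — enough that
matching demonstrably removes bias the raw comparison cannot. What the
generator does **not** emulate: survey non-response, measurement error in
self-reported service use, cluster sampling, or effect heterogeneity
across districts; passing tests show estimator behaviour under clean
confounding, not robustness to those features of real exit-interview
data.

**FX/CPI tables.** The study cites market exchange rates and the 2014
Ghana CPI but not the values; the package ships small synthetic tables
(GHS/USD drifting 1.90→3.20 over 2012–2014; CPI 78.0/87.8/100.0 with
2014 = 100). Lookups are exact-match; a missing month or year raises an
error rather than interpolating.

## Effect estimation

Propensity scores come from a maximum-likelihood logistic model of
treatment on the five covariates (statsmodels; marital status one-hot).
Perfect or quasi-separation falls back to an L2-regularized fit and sets
a diagnostic flag; scores are clipped to [1e−6, 1−1e−6]. Matching is
1:1 nearest neighbour **with replacement** — the standard ATT default,
which also makes the estimate invariant to record order — with score
ties broken by lowest record id and an optional caliper (default ∞;
treated units with no control inside the caliper are dropped and
tallied). Standard errors are a 500-resample nonparametric bootstrap
over treated records. No caliper, replacement rule or uncertainty
treatment is stated for the original analysis; these are this package's
documented defaults. Only the three significant outcomes (skilled birth
attendance, facility delivery, measles) are carried forward.

## Costing

Each ingredient carries a 10-year aggregate amount for the full
170-district rollout. Per-district rates divide by fixed reference
divisors: 170 districts for the one-time development and start-up
phases, and 1,347 implementation district-years (45 districts × 9 years
+ 67 × 8 + 58 × 7 from the staggered cohorts). This reproduces the
reference per-district rows — 4,110 development, 44,138 start-up,
17,918 implementation per year, 66,166 total — and keeping the divisors
fixed (rather than re-deriving them from the schedule passed in) makes
cost monotone: adding a district can only add cost.

Known arithmetic quirks of the source tables, carried deliberately:

* The development line items sum to 674,142 versus a printed subtotal of
  698,647; the residual 24,505 is shipped as an explicit "unallocated
  balance" item so phase subtotals and shares use the printed
  denominators.
* Start-up items sum to 7,503,509, one dollar above the printed subtotal
  (source rounding); items are carried as printed.
* The implementation personnel share computes to 46.48%
  (11,218,454/24,135,461) though the source narrative rounds it to 47%.
* The abstract-level "US $17,618 per district per year" sustaining cost
  is inconsistent with the table's 17,918 (= 24,135,461/1,347); the
  table value is used.
* A printed "mean annualized cost per district of US $237,745" is not
  derivable from any combination of the shipped figures and is not
  reproduced.

Variable drivers scale linearly relative to the Gomoa West anchor:
`per_facility` by (CHPS + health centers)/21, `per_nurse` by nurses/42,
`per_enrollee_year` by population (birth cohort at a common crude birth
rate). Linear scaling is the minimal choice consistent with costs that
"vary with the number of facilities and nurses". Phone replacement is
treated as a recurrent implementation item (3-year handset life folded
into the annual amount).

**Discounting.** The 3% rate enters the annuity factor and the YLL
formula. Cross-year present-value discounting of the cost and DALY
streams is available (`discounted_total`, config `discount_rate`) but
off for the headline totals, which mirror the reference accounting where
the US $32.3M figure is the undiscounted inventory sum.

## Coverage projection

Year-by-year stepping keyed to start-of-year coverage: full step below
75%, half step in [75, 90), quarter step at ≥90%, hard cap 99%. The
source states the thresholds but not the boundary convention; inclusive
upper-side boundaries are used (so a district at exactly 90% steps at a
quarter rate). The endline effect is spread over the first **2**
implementation years (the source does not print the within-horizon
increment; a 2-year linear ramp is this package's documented
assumption), and district trajectories begin the year after the
development/start-up year — hence no lives saved in year 1.

## Impact engine

The cohort software used in the original forecast (a proprietary
lives-saved tool) is replaced, not wrapped, by a linear attributable-risk
engine with a residual-mortality correction:

    averted(d, t, i, o) = D₀(d, o) · a(i,o) · e(i,o) · Δcov(d,t,i)/100
                          / (1 − e(i,o) · cov₀(i)/100)

summed over interventions i. D₀ is the annual baseline envelope from
births × rates (MMR 380/100,000; under-five 49/1,000; stillbirths
22/1,000 — the stillbirth rate is not printed in the source and is a
configurable era-typical value). The denominator removes deaths already
prevented at baseline coverage so a move 20→40% with 50% efficacy averts
88.9 of 1,000·0.8 addressable deaths, not 80.

Efficacies and affected fractions ship as editable defaults chosen to be
generous (high e, moderate a) so that the **calibration mode** — which
rescales each outcome's affected fractions by a common factor to hit
user-supplied 10-year anchor totals (6,298/33,797/19,811) — keeps every
fraction within [0, 1] with ~30% headroom against weaker estimated
effects. Because the engine is linear in the affected fractions,
calibrated totals match the anchors exactly. Per-year paths, by
contrast, are a genuine model output: the original tool's internal ramp
is unpublished, so the published year-2 (483) and year-10 (11,938)
values are not forced and this package's per-year profile differs (its
year-2 total is ≈1,200 under the 2-year ramp at the default seed).

**DALYs.** YLL only, continuous discounting `(1−e^{−rL})/r` at r = 3%:
28.66 years per under-five death or stillbirth (L = 65.5), 22.18 per
maternal death (remaining L = 36.5 = 65.5 − mean maternal age 29,
configurable). Stillbirths accrue YLLs like neonatal deaths by default
(config switch to exclude). The published 1,550,028 DALY total is not
reconstructible from 59,906 deaths under any single stated (L, r); this
package's total, 1.68M, implies 28.0 DALYs per life saved, inside the
plausible [22, 29] band that brackets the published implied ratio 25.9.

## CEA and uncertainty

ICERs are reported per year and cumulatively; a positive-cost,
zero-effect scope yields a typed undefined record, never an infinity.
Threshold verdicts: ICER < 1× per-capita income → highly cost-effective,
< 3× → cost-effective, boundaries to the weaker class.

The PSA samples cost items from gamma distributions (mean = base,
SD = 20% of base — non-negative and right-skewed, standard for costs),
and coverage effects from normals truncated to [0, 100] with SD such
that the 95% interval spans ±40% of the effect. The source names
neither families nor spreads; these are conventional defaults, all
exposed in config. 1,000 iterations re-evaluate the full model through
a pre-aggregated closure that is algebraically identical to the
stage-by-stage pipeline (tested to 1e−9). The point estimate is mean
cost ÷ mean effect with a percentile 95% CI of the per-draw ratio.
Invalid draws (no effect) are resampled with a counter; more than 1%
resamples aborts. One-way analysis sweeps each parameter ±20% (again a
conventional, unstated-in-source choice), ranks by ICER span with
alphabetical tie-break, and the tornado consistently ranks the
health-effect/lives-saved parameters and implementation personnel costs
at the top — the same qualitative ordering the original uncertainty
analysis reports. The CEAC uses the net-monetary-benefit rule on a WTP
grid {0, 50, 100, 200, 400, 800, 1480, 4440} US$/DALY.

## Numerical conventions and degenerate inputs

Deterministic tie-breaks throughout (record-id for matching ties,
alphabetical for tornado ties); all randomness flows from
`numpy.random.default_rng(seed)` and identical seeds give byte-identical
outputs. Coverage projection rejects negative increments; the engine
rejects efficacy × baseline coverage ≥ 100%; empty schedules yield empty
(all-zero) streams; intercept-only propensity fits return the treated
share for every record.

## Problem sizes

The reference configuration used across tests and the acceptance script
is the study-scale one: 170 districts, 5,000 interview records per arm,
1,000 PSA iterations, 10-year horizon. A full run takes a few seconds;
parameter-recovery checks average 20 generator seeds.

## Limitations

Program-perspective costs only (no client time or travel); no coverage
decay or heterogeneous district baselines beyond config; no
cause-of-death detail beyond the three outcomes and no disability
weights; the impact engine is a transparent simplification, not a
replication, of the original cohort tool, so per-year lives-saved paths
and probabilistic published values (US $20.94/DALY, US $586.72/death,
per-outcome CEAC probabilities) are neighbourhood-comparable but not
targets. Matching quality depends on propensity overlap; the generators
produce strong overlap by construction.
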