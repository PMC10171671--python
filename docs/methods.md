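# Methods

This note documents the models, parameter choices, numerical decisions and
limitations behind `sodium_cra`.  It is written for a reader who wants to
judge what the package computes and what its tests do and do not
demonstrate.

## The causal pathway

The package implements a comparative risk assessment (CRA) of dietary
sodium on cardiovascular mortality through one intermediate factor,
systolic blood pressure (SBP):

    salt intake (g/day)  --beta-->  SBP (mmHg)  --RR20-->  CVD death

* **Units.**  Sodium appears in mg/day only at the I/O boundary; all risk
  computation is in grams of salt per day, salt = sodium × 2.5 / 1000
  (2,300 mg/d sodium = 5.75 g/d salt).
* **Salt → SBP** is linear with an age-specific slope β (mmHg per g/day of
  salt).  The bundled slopes rise from ≈0.51 (ages 15–29) to ≈1.37
  (70+), transcribed from the age-specific blood-pressure response to a
  100 mmol/day sodium change in the Law, Frost & Wald (1991) analyses; no
  dependence on baseline SBP is modelled (a simplification — the
  underlying analyses show larger responses at higher starting pressure).
* **SBP → mortality** is log-linear: each cause group carries a relative
  risk per 20 mmHg of usual SBP, RR₂₀, by age at risk.  Ischaemic heart
  disease and stroke entries invert the Prospective Studies Collaboration
  age-specific "per 20 mmHg lower" hazard ratios (Lewington et al. 2002);
  the remaining pressure-mediated cause groups (heart failure,
  hypertensive disease, aortic aneurysm, pulmonary embolism, rheumatic
  heart disease) are not tabulated cause-by-cause there, and their
  entries are approximate transcriptions anchored to the Collaboration's
  "other vascular" gradient; their source strings say so.  No floor or
  ceiling is applied to the extrapolation in either direction.

Parameters are **data, not code**: they live in a versioned YAML/JSON file
with per-entry provenance strings, validated on load (β ≥ 0, RR₂₀ ≥ 1,
CI brackets the estimate, full cause coverage).  Age resolution maps a
5-year mortality band to the slope/RR age range containing its midpoint,
with nearest-range fallback (the 85+ band uses midpoint 87.5).

## Potential impact fraction

For a stratum whose usual-intake distribution shifts from baseline F_b to
counterfactual F_c, with k = ln(RR₂₀)/20 · β,

    PIF = 1 − E_c[exp(kX)] / E_b[exp(kX)],

independent of the reference intake (which cancels from the ratio).
Deaths averted in a mortality cell = observed deaths × PIF; the
counterfactual cell deaths are conserved as deaths − averted.  Totals are
sums over the seven mutually exclusive ICD-10 cause groups; under-75
subtotals sum the bands below age 75.

**Exposure forms.**  The default form is a normal distribution truncated
at zero and renormalized, for which E[exp(kX)] has the exact expression
exp(μk + σ²k²/2)·Φ(μ/σ + σk)/Φ(μ/σ); this is the fast vectorized path.
Adaptive quadrature over the density is available (`method="quadrature"`)
and the two paths are cross-checked to 1e-8 in the tests.  A lognormal
form is supported; because the raw lognormal has no moment-generating
function (E[exp(kX)] diverges), lognormal expectations are taken under
the distribution truncated at ±8σ in log space and renormalized — a mass
of ~1−1e-15, numerically irrelevant at realistic k but mathematically
necessary.

**Mean-shift mode.**  `mean_shift_only=True` replaces the expectation
ratio by exp(k·(μ_c − μ_b)): the population mean SBP change applied
uniformly, ignoring changes in the intake distribution's spread.  The
engine's default integrates over the distributions, which is the more
complete treatment; the mean-shift mode exists because published
PRIME-style analyses are consistent with it, and because scenario SD
columns derived from standard errors of survey models can be erratic
(the bundled reference table contains a reformulation-scenario SD larger
than its baseline SD in one stratum and implausibly small SDs in others).
The package's reproduction of published headline totals — and therefore
`scripts/acceptance.py` and the headline acceptance test — uses the
mean-shift configuration; the distribution-aware totals are reported
alongside and run 10–30% higher, almost entirely because the published
reformulation-scenario SDs are much smaller than baseline.

**Monte Carlo uncertainty.**  Per iteration, one slope draw per β age
range (Normal around the point slope with its SE, negative draws
truncated to zero) and one ln RR₂₀ draw per (cause, age-range) entry
(Normal with the SE implied by the 95% CI), shared across sexes and
mortality cells — a deliberately conservative correlation structure that
widens rather than narrows the intervals.  UIs are the 2.5th/97.5th
percentiles of 10,000 per-group totals; runs are reproducible
bit-for-bit under a fixed seed, and independent seeds agree within 2%
relative on the interval bounds.

## Intake scenarios

* **Proportional scenarios** (population target T): every stratum mean
  and SD is multiplied by r = T / x̄_pop, so the survey-weighted
  population mean lands exactly on T and each stratum's coefficient of
  variation is preserved.  The population baseline mean defaults to the
  weighted mean of the stratum means but can be supplied externally (the
  bundled reference table's all-ages mean is 2,758 mg/d, and using it
  reproduces the published per-stratum counterfactual means to ±1 mg/d).
  If T is at or above the baseline mean there is nothing to reduce: the
  ratio is clamped at 1 with a warning.
* **Reformulation scenario**: re-prices every recall day against the
  capped food-supply profiles and re-estimates the stratum distributions,
  so its effect size is an output of the food supply, not an input.

**Usual-intake estimation** is a moment-based stand-in for full
measurement-error modelling of repeat 24-h recalls (the National Cancer
Institute method): the stratum mean is the survey-weighted mean of person
means, and the between-person (usual) variance is

    max( var(person means) − within-person variance / mean days, floor )

with the within-person variance pooled from respondents with two recall
days.  Strata with no repeat recalls fall back to the total variance of
person means with a logged warning.  The variance floor (default 1 mg²)
keeps the SD positive in degenerate data.  This stand-in ignores recall
sequence, weekday/weekend and misreporting covariates, and slightly
over-corrects when recall counts vary across respondents (it divides by
the mean number of days rather than averaging 1/days); parameter-recovery
tests show the configured between-person SD is recovered within 10% at
n = 2,000 two-day respondents.  Energy misreporting is classified from
reported energy vs estimated energy requirement with the conventional
cut-offs: ratio ≤ 0.70 under-reporter, > 1.42 over-reporter.

**DRI cut-point statistics** count survey-weighted proportions with usual
intake ≤ AI (1,500 mg/d; the boundary counts as at-or-below) and
strictly > CDRR (2,300 mg/d).

## Reformulation engine

Capping is min(density, target) per product, flagged per product;
products without a category or whose category has no published target
pass through unchanged (benchmark target lists never cover the whole
food supply).  Capping is idempotent, never increases a density, and the
capped set is exactly {density > target} — all property-tested.  Profile
aggregation is an unweighted mean over matched products (sales-weighted
aggregation is out of scope); unmatched profiles keep their generic
database density.  Because capping only lowers densities, every
respondent-day intake is monotonically non-increasing under the
reformulation counterfactual.

## Synthetic data

The generators emulate the statistical structure the analysis relies on,
not the real data themselves:

* **Recalls** — person usual intakes are lognormal, moment-matched to
  each stratum's configured mean/SD (defaults: the bundled Canadian adult
  baseline table, survey-n weights); each respondent has a first recall
  day and 35% a second; day intakes multiply mean-preserving lognormal
  within-person noise with CV 0.4 (no published value exists for this
  pipeline's inputs; 0.4 is typical of the within-person variation of
  sodium in repeat 24-h recalls).  An additive-noise mode with a fixed
  within SD exists for parameter-recovery experiments.  Day totals are
  decomposed into 8 items across profiles by Dirichlet shares, so
  re-pricing items against a capped supply is exact.
* **Food supply** — per category a target is drawn from 100–1,200 mg/100 g
  and each product lands above it with a configurable probability
  (default 0.5, uniformly 1.05–1.8× the target when above).
* **Demography** — deaths by sex × 5-year band × cause with a log-linear
  age gradient (default 0.10/year, putting ≈41% of deaths at 85+ and
  ≈22% under 75, realistic for cardiovascular mortality), split across
  causes with ischaemic heart disease dominant (53%), then stroke (23%),
  heart failure (10%), hypertensive disease (7.5%), aortic aneurysm
  (3.5%), pulmonary embolism (2%), rheumatic heart disease (1%); sex
  totals default to 30,663 men and 27,813 women (58,476), the
  reference-year totals, hit exactly by largest-remainder rounding.
  A gradient of zero gives uniform deaths across bands.
* Child strata (ages 1–18) can be generated for descriptive outputs but
  never enter the impact model, which is adults-only.

What passing tests on these data do **not** show: robustness to real
survey design (clustering, calibration weights, bootstrap replicate
weights), to covariate-driven reporting biases, to seasonal or weekday
effects, or to food-matching error between branded products and recall
profiles — none of which the generators emulate.

## Problem sizes and runtime

The default test suite runs at desk scale: 196 mortality cells (2 sexes ×
14 bands × 7 causes), 8 adult strata, synthetic cohorts of 150–5,000
respondents, and Monte Carlo runs of 10,000 iterations on the vectorized
truncated-normal path (a 10,000-iteration scenario takes well under a
second).  `scripts/acceptance.py` uses the full 10,000 iterations.

## Known limitations

* Static, same-year model: no time lag between exposure change and
  mortality, no morbidity, life-years or DALYs, no costing.
* CVD only, via blood pressure only — sodium-related outcomes such as
  chronic kidney disease and gastric cancer are out of scope, so impact
  estimates are conservative.
* The salt→SBP slope ignores baseline-SBP dependence; the RR₂₀ entries
  for five of the seven cause groups are approximate transcriptions.
* Totals are exclusive sums over ICD-10 cause groups; published
  macrosimulation totals that adjust for double counting can sit slightly
  below such sums.
* The usual-intake stand-in is moment-based, not a nonlinear
  mixed-effects measurement-error model; percentiles beyond what the
  assumed distribution form implies are not estimated.
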