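# Methods

This note documents the statistical model, the harmonization rules, the
synthetic-data generator, and the numerical and design choices behind
`noisesleep`.

## The quantity being modelled

%HSD — the percentage of highly sleep-disturbed residents — is defined by a
cutoff on the ordinal response continuum, following the convention of the
annoyance literature: a respondent counts as "highly" disturbed to the
extent their rating falls in the top ~28% of the continuum (cutoff 72%).
Because surveys use different scales, the cutoff is applied through
**converted scores**: category *i* of a *k*-point scale occupies
[(i−1)/k, i/k], and its score is the fraction of that interval above the
cutoff. At cutoff 0.72:

| scale | converted scores | effective cutoff |
|---|---|---|
| 2-point | (0, 0.56) | 72% |
| 4-point (top-only) | (0, 0, 0, 1) | 75% |
| 5-point | (0, 0, 0, 0.4, 1) | 72% |

The 4-point frequency scale is the one deliberate exception to the overlap
formula: only its top category is counted (flag `top_only` in the registry),
giving an effective 75% cutoff. The general formula is the implementation;
the table above is a fixture test of it.

Respondents rating several items (difficulty falling asleep, nocturnal
awakening, …) get the **mean** of the item scores by default; e.g. ratings
(5, 4) on the 5-point scale give (1 + 0.4)/2 = 0.7. A `max` combination
rule is available as a configuration option because both conventions appear
in the meta-analysis literature; the mean is the default and the only rule
used in tests. %HSD for a group is 100 × (sum of scores) / n — fractional
scores, not binarized labels, feed all aggregation and curve fitting.

## Analysis set

Included respondents live in detached houses (apartment insulation differs
too much for outdoor-level analysis), have a resolved night level
L_night ≥ 30 dB (boundary inclusive), and answered at least one
sleep-disturbance item. The filter is total and idempotent and reports
per-reason exclusion counts.

## Exposure

L_night is the A-weighted equivalent level over 22:00–07:00. When a dataset
supplies only L_den:

* **road**: L_night = L_den − Δ, with Δ the dataset's measured day–night
  difference (a calibration input, never computed here);
* **rail**: assuming equal per-event sound exposure across periods, the
  period level is L_p = E + 10·log10(N_p/T_p) for timetable counts N_p and
  durations T_p; solving the L_den energy balance for E gives

      L_night = L_den − 10·log10( Σ_p N_p·10^(pen_p/10) / 24 )
                      + 10·log10( N_night / T_night ).

  A timetable with zero night events leaves L_night undefined and the
  respondent is excluded. The closed form is verified in tests against an
  independent hourly energy-summation oracle to < 1e−9 dB.

Period boundaries/penalties default to the standard L_den convention
(day 07–19 +0, evening 19–22 +5, night 22–07 +10 dB) and are configurable;
only the night window is fixed by the metric's definition.

Levels are classed into 5-dB **NL** bins centered at 33…78 dB by nearest
center; the class boundaries are the midpoints, with exact midpoints
assigned upward (class 53 covers (50.5, 55.5]; in integer dB, 51–55).

## Suppression

Per-dataset table cells with n < 25 are suppressed (printed as missing);
pooled (source, NL) classes with n < 50 are flagged and excluded from curve
fitting. Suppression removes rows only; retained values are unchanged.
Per-dataset percentages are rounded half-up to integers; pooled fitting uses
unrounded proportions.

## Exposure–response curve

For pooled class proportions p_i with sizes n_i at centers NL_i, the model
is p(NL) = expit(b·NL − a). The default estimator (``wnls``) minimizes
Σ n_i (p_i − p(NL_i))², started from the n-weighted logit-linear regression
and solved by Levenberg–Marquardt with parameter tolerance 1e−12; a
coarse-to-fine grid-search oracle in the tests guards against local minima.
The parameter covariance is σ̂²(JᵀWJ)⁻¹ with σ̂² = weighted RSS/(m−2).
The alternative ``binomial_glm`` maximizes the binomial likelihood with
successes round(hsd_sum_i) of n_i trials. Both are implemented; **wnls is
the documented default because it reproduces the published reference
coefficients on the packaged aggregate** (RT a≈5.64, b≈0.0600) while the
GLM, which weights classes by p(1−p) leverage rather than purely by n,
lands visibly elsewhere on the railway sources (CR slope 0.067 vs 0.054).
The two agree exactly in the zero-residual limit, which is tested.

Goodness of fit is the n-weighted R² = 1 − Σn(p−p̂)²/Σn(p−p̄_w)² with the
weighted mean as null model; it can be negative and is undefined for zero
weighted variance (an error).

Confidence bands are delta-method intervals on the linear predictor
η = b·NL − a (gradient (−1, NL)), mapped through the logistic — so bands
always bracket the point estimate and collapse to it under zero covariance.
This is the package's definition of the interval; it is validated against a
parametric Monte-Carlo resampling of (a, b) rather than against any
published interval table, whose construction is not documented and whose
high-level railway intervals are implausibly wide.

Fitting requires ≥ 3 classes and is invariant to uniform weight scaling.

## Binarization and the covariate model

Individual-level regression needs binary labels. Within each group of
identical score value s (grouped per dataset, so each survey's categories
split internally), exactly round_half_up(s·m) of the m respondents are
labeled HSD by a seeded shuffle ("exact split"); a Bernoulli(s) variant
exists for simulation work. Scores 0 and 1 map deterministically. The split
seed is a mandatory, logged input; seed-induced estimate variability shrinks
with sample size (tested).

The regression is maximum-likelihood logistic with terms: intercept, NL
(continuous, per dB), female (vs male), age 40–59 and ≥60 (vs <40), and
after-2010 (vs before; the collection spans ~2000–2023 and 2010 splits it).
Wald SEs and two-sided p-values; OR = exp(β) with 95% Wald CIs; AUC is the
Mann–Whitney form U/(n₁n₀) with ties counted half. The conventional
exposure effect size is the per-5-dB odds ratio exp(5β_NL) (≈1.3 at
β_NL≈0.052). Records with "no answer" gender or age are listwise-deleted by
default with the dropped count reported; `missing="category"` keeps them as
their own indicator levels — the published tables' n suggests the original
analyses kept them, but their treatment is not documented, so both
behaviours are provided and neither is asserted against published
coefficients.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes, with defaults
frozen to the observed study conditions: per-source NL class frequencies
and gender/age mixes from the packaged aggregate fixtures, dataset (and
hence scale) mix proportional to the registry sample sizes, survey years
drawn from each dataset's registry range, and dose–response parameters
defaulting to the published per-source curves. Levels are drawn uniformly
within the respondent's NL class (truncated at 30 dB).

Each respondent's HSD probability is π = expit(b·L − a + x'β) with
configurable demographic/period log-odds offsets (default 0). Ordinal
categories are drawn to match the **converted-score expectation**: on
5-point scales P(top) = ρπ and P(4) = (1−ρ)π/0.4 (default ρ = 0.5), so
P(top) + 0.4·P(4) = π per item; on 2-point scales the affirmative
probability is π/0.56 (capped at 1 with a warning — the cap only binds when
π > 0.56); the top-only 4-point scale uses P(top) = π. Sub-cutoff mass is
spread over the lower categories in fixed proportions, which affects
nothing the analysis consumes. A cumulative-logit (`ordered_logit`) draw is
available for realism experiments; it does not preserve the expectation
identity and is never a test default.

What passing tests on this generator do show: the scoring, binning,
pooling, fitting and regression machinery recover known parameters from
data with the collection's marginal structure. What they do not show:
robustness to real-data features the generator omits — exposure measurement
error, within-dataset spatial clustering, item-level correlation beyond the
shared π, non-logistic dose–response, and differential nonresponse.

## Problem sizes and tolerances in the test suite

The end-to-end recovery test generates 100,000 respondents per replicate
and averages five seeded replicates: the single-replicate Monte-Carlo SD of
the recovered slope (~0.001) equals the recovery tolerance (±0.001), so the
ensemble mean is the adequately-powered form of the same check; a separate
200-replicate study verifies unbiasedness at the observed class sizes. The
null-coverage test uses 200 replicates of n = 1500 and accepts 180–199/200
intervals covering OR = 1 (±3 binomial SEs around 190). Curve fits
reproduce the reference coefficients within ±0.3 (intercept) and ±0.004
(slope) — the slack absorbs the integer rounding of the packaged %HSD
aggregate, the only published form of the fitting input; predictions at
reference levels are checked to ±0.3 percentage points at the points where
that rounding slack cannot dominate (mid-range of each source's fitted
span).

## Known limitations

* The packaged pooled aggregate carries integer-rounded %HSD; fits from it
  differ from the original microdata fits in the third decimal of the slope.
* The day–night differences and timetables of the original datasets are not
  published; exposure conversion parameters are user inputs.
* No survey weighting, no dataset-level random effects, no noise-map or
  propagation modelling, and no L_Amax-based analysis (the archived
  microdata carry only equivalent levels).
* Confidence bands are asymptotic (delta method / Wald); with only 4–9
  classes per source the intercept SEs are large and the bands should be
  read accordingly.
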