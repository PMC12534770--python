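# Methods

This note documents the models, conventions, and design choices behind
climaffect, in the spirit of a statistical package's model documentation.

## Lexicon scoring

Scores follow the word-count convention: a category's score for a post is
100 × (tokens matching the category) / (total tokens). Entries are literal
words or stems (`happ*`) matched by prefix. Tokenization is whitespace
splitting with punctuation stripping and case folding for space-delimited
scripts, or a greedy maximal forward match against the lexicon vocabulary
with single-character fallback for scripts without word delimiters. A
zero-token post scores 0 in every category.

Derived measures:

- **Expressed emotional well-being (EWB)** = posemo% − negemo%, in
  [−100, 100]. Higher is more positive.
- **Analytic-thinking composite** = 30 + articles + prepositions −
  personal pronouns − impersonal pronouns − auxiliary verbs − conjunctions
  − adverbs − negations, on the raw (unclamped) scale. The weights are
  fully configurable; this default is the published function-word
  composite for analytic thinking. The exact operationalization used with
  licensed Chinese dictionaries is not public, so this is a documented
  stand-in, as is the somatosensory default (body% + feel%).
- **Pro-environmental flag**: 1 iff any phrase from seven behaviour
  groups (saving energy, consumption, activism, recycling, transportation,
  diets, waste management) occurs as a case-folded substring of the raw
  text. Substring (not token) matching is deliberate: multi-word phrases
  would be split by tokenization.

Licensed dictionaries (LIWC and relatives) cannot be redistributed; the
bundled lexicon is a small synthetic demonstration vocabulary in an open
plain-text format into which a licensed dictionary can be exported.

## Extreme-weather indicators

Per region, a multi-year baseline yields the 10th and 90th empirical
percentiles of daily mean temperature (linear interpolation between order
statistics — conventions differ across software, so this is pinned), the
90th percentile of precipitation on wet days (precip > 0), and
calendar-month means. Flags use strict inequalities: a day exactly at a
threshold is not extreme, and hot/cold are mutually exclusive. Scoring a
baseline against its own climatology therefore flags ~10% of days in each
temperature extreme class, up to ties and interpolation.

Thresholds default to the whole-year baseline distribution; a monthly
stratification (`window="month"`) is available for users who want
within-season extremes. `temp_change` is the anomaly from the region's
baseline mean for that calendar month, so it is seasonality-adjusted;
the analogous `precip_change` uses monthly mean precipitation. Whether
extremes should use daily mean or maximum temperature is a data question;
the implementation takes `tmean` and callers may supply `tmax` in that
column if preferred. Seasons are meteorological (Dec–Feb winter, Mar–May
spring, Jun–Aug summer, Sep–Nov autumn), with spring the reference level
in regressions.

Missing-value sentinels common in daily-summary exports (9999.9 etc.) are
mapped to missing on read; rows with missing temperature get missing
indicators and are counted, not dropped silently.

## Merge and dichotomization

The analysis table is an inner join of scored posts to (region, date)
indicators and then to region vulnerability, with explicit drop accounting
and the invariant matched + dropped = input asserted per run. Duplicate
(region, date) indicator rows are a hard error (ambiguous join).
Vulnerability indices are dichotomized at the cross-region median with a
strict inequality — the median region itself is "low" — matching the
"higher than the median" reading. Missing index values are excluded from
the median and propagate as missing flags.

## Mixed correlations

Continuous–continuous pairs get Pearson's r; continuous–binary pairs the
point-biserial coefficient; binary–binary pairs the Matthews (phi)
coefficient. Both special cases are numerically Pearson's r on 0/1
codings, and are computed that way; tests verify equality with the
closed-form group-mean-difference and cross-product formulas to 1e-12.
One p-value formula is used for all three: t = r·√((n−2)/(1−r²)) on n−2
degrees of freedom, two-sided. Phi is sometimes tested with χ² instead;
the t form was chosen for uniformity across the matrix. The
Benjamini–Hochberg family is all upper-triangle tests of one matrix — the
most conservative reading when the family is not otherwise defined.
Missing data are deleted pairwise and the per-pair n is reported;
zero-variance pairs are reported as missing with a reason and excluded
from the FDR family.

## Mediation path model

Five observed variables: exposure x (extreme-hot flag or temperature
anomaly), three mediators, outcome Y. The model is recursive and linear
with free residual covariances for (mediator 1, mediator 2) and
(mediator 1, mediator 3); the (2,3) residual covariance is fixed at zero.
That pair of free covariances is part of the specification, not searched
for at run time.

**Estimation.** Equation-wise least squares: each mediator on x, Y on x
plus all mediators. Residual (co)variances use denominator n. For this
recursive specification the least-squares coefficients coincide with the
maximum-likelihood path solution, so no iterative optimizer is involved;
the ML discrepancy F = ln|Σ̂| − ln|S| + tr(S·Σ̂⁻¹) − p is evaluated at
these estimates, with χ² = (n−1)·F. Free parameters: 3 a's, c′ and 3 b's,
var(x), 3 mediator residual variances, 2 residual covariances, 1 outcome
residual variance = 14, so df = 15 − 14 = 1. The baseline model for CFI is
the independence (diagonal) model; GFI = 1 − tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²];
RMSEA = √(max(χ²−df, 0)/(df·(n−1))).

**Bootstrap.** Case resampling of whole rows, B = 1000 by default, seeded.
A replicate with constant exposure is redrawn and counted; more than 10%
redraws aborts the run. Per effect: bootstrap SE is the SD of replicate
estimates; the BCa interval uses z0 = Φ⁻¹(fraction of replicates below
the point estimate), clamped to [1/(B+1), B/(B+1)], and acceleration from
the skewness of leave-one-out jackknife values. The jackknife is computed
with the exact closed-form leave-one-out least-squares update (hat-matrix
downdate), which is algebraically identical to n refits at a fraction of
the cost, and is what makes the coverage simulation practical. Quantiles
use linear interpolation. The two-sided p-value is the smallest level at
which the BCa interval excludes zero, searched on a grid of step 1e-4, so
reported p-values are floored at 1e-4. With z0 = 0 and â = 0 the interval
reduces exactly to the percentile interval (tested).

Unstandardized coefficients are reported. No covariates enter the path
model; season and vulnerability effects are handled by the separate
moderation models.

## Moderation and nested logistic models

Moderation models are Gaussian linear regressions of EWB on a weather
term, a moderator, and their product. Factors are treatment-coded with
spring / "low" references; a single-level moderator degrades gracefully to
the exposure-only model. z = estimate/SE with normal p-values and Wald
CIs, matching the convention of reporting z statistics without robust or
clustered errors; clustering by region-day is a known omission (below).
Simple slopes at probe values v are β_exposure + β_interaction·v with SEs
from the coefficient covariance.

The pro-environmental outcome gets four nested logistic models adding
blocks cumulatively: weather → + EWB → + three cognitive scores → + four
vulnerability flags. Fits are maximum likelihood via statsmodels' Newton
scoring; odds ratios carry Wald CIs; McFadden pseudo-R² = 1 − ℓ/ℓ₀.
Nested log-likelihoods are monotone non-decreasing (tested). VIF
screening regresses each predictor on the others (intercept included),
removes the largest VIF > 5, and recomputes until all pass; perfect
collinearity reports an infinite VIF and is removed first. The removal
order (largest first) is a documented choice.

## Synthetic-data generator

The generator exists so that every stage has a known-truth oracle.

- **Weather**: tmean = μ + A·sin(2π(doy − phase)/365.25) + AR(1) noise,
  with innovations scaled so the stationary SD equals `noise_sd`
  (default 3 °C, AR coefficient 0.6 so extreme-day runs cluster like heat
  waves). Default μ staggers 12–24 °C across regions with amplitude
  10 °C. Precipitation is zero with probability 0.7, else gamma(0.8,
  scale 8 mm). Twenty baseline years by default, matching the length of
  record that percentile climatologies are typically built on.
- **Vulnerability**: one draw per region (log-normal population density,
  unit-interval indices).
- **Posts**: Poisson counts per region-day (simplest arrival model — the
  real-world count distribution over region-days is unknown, so Poisson
  is a stand-in, not a claim). Each post follows the linear structural
  model with trivariate Gaussian mediator residuals whose only free
  correlations are (1,2) and (1,3), mirroring the fitted model, and a
  Bernoulli pro-environmental flag from a logistic model on (x, Y, M).
  Default truth: a = (−0.5, −0.3, 0.2), b = (0.9, 0.3, 0.1), c′ = −0.2,
  total effect −0.72 by the identity c = c′ + Σ a_k·b_k. An optional
  summer×exposure interaction on Y supports moderation tests.
- **Text mode** emits token sequences whose category percentages score
  back exactly (fillers are out-of-lexicon; non-integer implied counts
  are an error, never rounded), giving the scorer a round-trip oracle.

What the generator does *not* emulate: realistic language, topic
structure, user-level repeated posting, spatial correlation between
regions, or weather–posting-rate dependence. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to the messiness of real corpora.

## Problem sizes and numerical choices

Parameter-recovery checks run at ~50,000 posts with B = 200 bootstrap
replicates; BCa coverage uses 300 simulated datasets of ~2,000 posts with
B = 500; the demo pipeline uses 4 regions × 1 year × rate 3 with B = 200.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances. Degenerate inputs are errors, not warnings: constant exposure,
non-positive-definite covariance (named matrix), short baselines (< 365
days, named region), duplicate region-days, miscoded binaries.

## Known limitations

- No clustering or autocorrelation correction for repeated posts within a
  region-day; SEs assume independent observations, as the reported-z
  convention implies.
- The path model is fully observed and linear; no latent variables,
  ordinal estimators, or multi-group fits.
- Station-to-region assignment is taken as given; no spatial
  interpolation.
- The analytic and somatosensory composites are documented stand-ins for
  proprietary dictionary definitions.
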