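# climaffect

Tools for studying how daily weather relates to the emotional well-being
people express in short social-media posts about climate change, and to
their stated pro-environmental tendencies.

The package is aimed at computational social scientists and environmental
epidemiologists who have (a) daily meteorological records per region, (b) a
corpus of geolocated, dated posts, and (c) region-level vulnerability
indices, and who want a reproducible chain from raw inputs to mediation and
regression results. Every stage can also run on synthetic data with known
ground-truth structure, so the statistical machinery is verifiable without
any proprietary corpus or dictionary.

## What it computes

**Lexicon scoring.** Posts are scored against a configurable category
lexicon in the word-count tradition: each category score is the percentage
of tokens matching the category's words or stems. The expressed emotional
well-being index is `EWB = posemo% − negemo%`. Three cognitive-response
measures are derived (social affiliation, an analytic-thinking composite
`30 + articles + prepositions − pronouns − auxiliaries − conjunctions −
adverbs − negations`, and a somatosensory score), plus a binary
pro-environmental flag from a seven-category keyword-phrase list.

**Extreme-weather indicators.** A multi-year baseline defines per-region
percentile thresholds: a region-day is *extreme hot* if its mean
temperature exceeds the baseline 90th percentile, *extreme cold* below the
10th, *extreme wet* above the wet-day 90th percentile; `temp_change` and
`precip_change` are anomalies from baseline calendar-month means. By
construction about 10% of baseline days fall in each extreme temperature
class.

**Mediation path model.** The core model is the recursive linear system

```
M_k = α_k + a_k·x + e_k            k = affiliation, thinking style, somatosensory
Y   = α_Y + c′·x + Σ_k b_k·M_k + e_Y
```

with the (affiliation, thinking-style) and (affiliation, somatosensory)
residual covariances free. Indirect effects are `a_k·b_k`, the total effect
is `c = c′ + Σ_k a_k·b_k`, and inference is a seeded case-resampling
bootstrap with bias-corrected and accelerated (BCa) confidence intervals
and interval-inversion p-values. Fit indices (χ², CFI, GFI, RMSEA) come
from the maximum-likelihood discrepancy between the sample and
model-implied covariance; the specification has one degree of freedom.

**Around the core:** mixed-type correlation matrices (Pearson /
point-biserial / Matthews with a single Benjamini–Hochberg FDR family per
matrix), moderation models with treatment-coded factors and simple-slope
probing, four nested logistic models for the pro-environmental outcome
(odds ratios, Wald CIs, McFadden pseudo-R²), and VIF screening with
iterative removal above 5.

## Worked example

Generate a year of synthetic data for three regions whose posts follow the
structural truth `a = (−0.5, −0.3, 0.2)`, `b = (0.9, 0.3, 0.1)`,
`c′ = −0.2` (so the true total effect is `−0.2 − 0.45 − 0.09 + 0.02 =
−0.72`), then fit the mediation model:

```python
import pandas as pd
from climaffect.simulate import (SyntheticConfig, generate_weather,
                                 generate_posts, generate_vulnerability)
from climaffect.weather import build_climatology, compute_indicators
from climaffect.merging import merge_analysis
from climaffect.mediation import PathModelSpec, bootstrap_effects

cfg = SyntheticConfig(n_regions=3, baseline_years=5,
                      posts_per_region_day_mean=10.0, seed=42)
weather = generate_weather(cfg)
clim = build_climatology(weather, cfg.baseline_start, "2021-12-31")
indicators = compute_indicators(weather, clim)
posts = generate_posts(cfg, indicators)
analysis, report = merge_analysis(posts, indicators, generate_vulnerability(cfg))
fit = bootstrap_effects(analysis, PathModelSpec(exposure="extreme_hot",
                                                n_boot=1000, seed=42))
print(fit.to_frame().round(3).to_string(index=False))
print(fit.fit)
```

Output (10,993 posts):

```
    effect  estimate    se  ci_low  ci_high   p
        a1    -0.512 0.029  -0.570   -0.456 0.0
        a2    -0.292 0.029  -0.350   -0.232 0.0
        a3     0.208 0.030   0.151    0.269 0.0
        b1     0.913 0.011   0.893    0.934 0.0
        b2     0.314 0.010   0.294    0.333 0.0
        b3     0.114 0.009   0.097    0.132 0.0
   c_prime    -0.194 0.028  -0.252   -0.140 0.0
indirect_1    -0.467 0.027  -0.521   -0.418 0.0
indirect_2    -0.092 0.010  -0.112   -0.072 0.0
indirect_3     0.024 0.004   0.017    0.032 0.0
     total    -0.729 0.042  -0.810   -0.644 0.0
{'chi_square': 0.266, 'df': 1, 'chi_square_baseline': 10785.386,
 'df_baseline': 10, 'cfi': 1.0, 'gfi': 1.0, 'rmsea': 0.0}
```

Every path estimate sits within two bootstrap SEs of its generating value;
the BCa interval for the total effect comfortably covers −0.72. The p
column is the smallest level at which the BCa interval excludes zero,
searched on a grid of step 10⁻⁴, so `0.0` here means p ≤ 10⁻⁴.

The same chain is available from the shell:

```sh
climaffect run-all --config src/climaffect/data/demo_config.yaml --out demo_out
```

which writes the indicator table, scored posts, analysis table,
correlation matrix, mediation report, moderation and nested-logistic
tables, and a `manifest.json` recording seeds, input hashes, and row/drop
counts.

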