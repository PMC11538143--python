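# Methods

## Scope and model

The pipeline treats monthly search volumes for a fixed set of WASH-related
query terms as a noisy public-interest signal and asks three questions:
whether per-term interest trends with time, how yearly total interest
relates to annual WASH indicators (access percentages, under-five
mortality, and a composite risk index derived from them), and whether the
volumes are large enough to stand in for a representative opinion survey.
All inferential statistics are rank-based, so every conclusion depends
only on orderings, never on the (unknown and re-estimated) absolute scale
of the volumes.

## Statistical conventions

These conventions are deliberately those of a spreadsheet-plus-online-
calculator desk study, because the quantities the pipeline is validated
against were produced that way:

- **Mid-ranks.**  Tied observations receive the mean of the rank positions
  they span; rank sums always equal `n(n+1)/2`.
- **Spearman ρ** is the product-moment correlation of the two mid-rank
  vectors.  For tie-free inputs this equals `1 − 6Σd²/(n(n²−1))` (tested to
  1e-12, plus a brute-force enumerated-rank oracle for small n).  The
  two-tailed p-value uses the t approximation `t = ρ·√((n−2)/(1−ρ²))` with
  `n−2` degrees of freedom, clamped to [0, 1]; perfect rank agreement maps
  to p = 0 by convention.  No exact permutation p-values and no
  multiple-testing correction are offered, matching the validated
  workflow.  Sequences with zero rank variance raise a degenerate-sequence
  error rather than returning NaN.
- **Variance percentage** is `100·ρ²`, reported as the share of the
  dependent variable's rank variance explained.
- **Kruskal–Wallis H** uses pooled mid-ranks with the tie-correction
  divisor `1 − Σ(t³−t)/(N³−N)` and a chi-square (k−1 df) p-value.  When
  every pooled value is identical the divisor vanishes and H is defined as
  0 with p = 1.
- **Normality screen.**  One-sample Kolmogorov–Smirnov against a normal
  with mean and n−1 standard deviation fitted from the sample; D is the
  ECDF supremum evaluated on both sides of every jump; p comes from the
  asymptotic Kolmogorov distribution at `√n·D` *without* the Lilliefors
  small-sample correction.  With estimated parameters this p is
  anti-conservative; it is used as a screen to justify rank methods, not
  as a calibrated test, which is why the package keeps the uncorrected
  convention.
- **Mode** is the exact-value mode with ties broken by first occurrence in
  input order — spreadsheet `MODE` behaviour, meaningful for count data
  where exact repeats (including repeated zeros) occur.
- **Report precision** mirrors the reference tables: ρ to 5 d.p., p to
  5 d.p., variance to 2 d.p., composite index to 1 d.p., relative share to
  3 d.p., sample-size population share to 4 d.p.  Internal computation is
  always full precision; rounding happens only at the report boundary.

## Index definitions and parameters

- **COV** (extraction stability, %): `100·|value − average|/average` per
  month, `average` being the mean of the two extraction occasions.  With
  exactly two occasions the value is occasion-symmetric, so one number per
  month is stored.  A month where both occasions are zero has no defined
  COV: such months are carried explicitly in the result
  (`undefined_months`) and excluded from the mean ± SD summary; only when
  *every* month is undefined does the computation refuse with an error
  listing them.  COV is bounded in [0, 200).
- **Yearly total** (`ytwrmt`): sum over all terms of the 12 monthly
  volumes of a calendar year.  Partial years are rejected unless
  explicitly allowed, because a partial total is not comparable across
  years.
- **Composite risk index** (`rdwdr`): `scale·mortality / (0.45·water +
  0.45·sanitation + 0.10·handwash)` with scale 100.  The weights encode an
  expert judgement that piped-service access dominates hand-washing
  facility access as an interest driver; they must sum to 1 and are
  configurable via `RdwdrWeights`.  Missing hand-washing access is
  zero-substituted here only.  The index is homogeneous of degree 1 in
  mortality and −1 in a uniform access rescaling (property-tested).
- **Relative share** (`ptssa`, %): `100·ytwrmt·world_pop·world_internet% /
  (global_searches·national_pop·national_internet%)`.
- **Sample size** (`necessary_sample_size`): `⌈z²p(1−p)/e²⌉` with the
  exact two-sided normal quantile (1.959964 at 95%; the conventional 1.96
  yields the same integer).  No finite-population correction: at national
  population scales it changes nothing, and the reference values are
  constant across years.

## Missing-data policy

"Not reported" is a first-class state distinct from zero throughout the
package.  The correlation study excludes missing years for the
hand-washing column (default policy `exclude`, n = 9 reported years in the
packaged table) because zero-filling injects a spurious block of tied
zeros into the early years and changes the coefficient; the alternative
`zero` policy is available for sensitivity analysis.  Inside the composite
index the zero substitution *is* applied, following the convention of the
reference table's footnote — the n = 17 index column is only reproducible
that way.

## Synthetic data generator

The generator emulates the statistical structure the analysis consumes,
not the marginal realism of search data:

- **Monthly series**: `value_t = round(max(0, a + b·t + ε_t))` with
  Gaussian ε.  The nine default terms are calibrated so that, over a
  222-month window, each term's mean, standard deviation and trend
  correlation match the observed per-term statistics (solving
  `mean = a + b·t̄`, `var = b²·var(t) + σ²`, `b·sd(t)/σ = ρ/√(1−ρ²)`);
  negative intercepts with the zero clamp reproduce the all-zero early
  months (and hence the zero modes) of the rarer terms.  The additive-
  Gaussian-then-clamp count model was chosen over a count-distribution
  model for transparency: the pipeline consumes ranks, so the noise family
  is immaterial to the statistics under test.
- **Repeat extraction**: `second_t = round(max(0, value_t·(1+η_t)))` with
  relative jitter η ~ N(0, 0.05) by default, giving a mean monthly COV
  near 2% (measured 2.02 across the nine default terms at seed 0).
- **Indicator tables**: logistic access trajectories (water high-80s →
  mid-90s %, sanitation low-60s → ~80%), an 8-year initial missing block
  then a logistic 40–62% band for hand-washing access, exponential
  mortality decay (78 → ~31 deaths per 1000 live births at rate
  0.055/yr), and yearly totals aggregated from a generated monthly panel.
- **Determinism**: a single seed governs everything; each stream (per-term
  series, per-term jitter, indicator table) derives a child generator from
  the seed plus a CRC32-keyed `SeedSequence` spawn key, so regenerating one
  piece never shifts another, and integer outputs make runs reproducible
  across platforms.

What passing the synthetic tests does **not** show: the generator has no
seasonality, no pandemic shocks, no autocorrelated noise and no realistic
marginal distributions, so recovery results demonstrate the pipeline's
correctness on trend-plus-noise structure, not robustness to real search
dynamics.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 seeded replicates: trend-sign recovery on
120-month single-term panels (slope 2 counts/month against noise SD 300)
and mortality-association sign recovery on full default tables (17 years,
nine terms); both recover the injected sign in ≥ 95% of replicates.  Rank
correlations snap |ρ| within 1e-12 of 1 to exactly ±1 so that perfect rank
agreement triggers the p = 0 convention despite floating-point noise.
Report writers emit fully deterministic bytes (fixed column orders, fixed
formats) so identical inputs give identical files.

## Known limitations

- The per-term reference statistics (means, COV rows, K-S statistics, the
  pooled across-terms H) depend on monthly series that were never
  deposited; the machinery is therefore validated against hand-worked
  examples, independent library oracles and synthetic recovery, not
  against those printed rows.
- The t-approximation Spearman p is inaccurate below n ≈ 10; it is kept
  because it is the convention of the workflow being reproduced.
- The global-context table's worldwide search totals are literature
  estimates of uneven quality; they are treated as inputs, never
  re-derived.
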