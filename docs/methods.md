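# Methods

`refrange` estimates reference intervals (RIs) for fasting insulin and the
HOMA-IR index indirectly, from mixed routine laboratory data. This note
documents the statistical model, the defaults and why they were chosen,
what the synthetic validation does and does not demonstrate, and the known
limitations.

## The estimation model

The post-filter analyte distribution is modeled as a finite mixture whose
dominant component is the physiological (healthy) subpopulation — the core
assumption of any indirect RI method. The pipeline
(`refrange.estimate.run_indirect_ri`) composes seven stages; every stage
records its output in the returned estimate, so results are auditable.

**Outlier removal** uses the medcouple-adjusted boxplot on the raw scale:
with medcouple MC ≥ 0 (right skew) the fences are
`[Q1 − 1.5·e^(−4·MC)·IQR, Q3 + 1.5·e^(3·MC)·IQR]`, mirrored for MC < 0.
The asymmetric stretch prevents mass-deleting the legitimate upper tail of
a right-skewed insulin distribution (a plain Tukey fence flags several
percent of a clean lognormal sample; the adjusted fence flags ≲ 1%). The
medcouple kernel is quadratic in n, so above 5,000 points it is computed on
5,000 evenly spaced order statistics — a deterministic thinning that
preserves the quantile structure the statistic depends on.

**Transform selection**: the sample is left untransformed when
|skewness| ≤ 0.5 and |excess kurtosis| ≤ 1; otherwise a Box-Cox transform
with λ from the coarse grid {−1, −0.5, 0, 0.5, 1} minimizing the absolute
skewness of the transformed sample (λ = 0 is the log). A coarse grid is
deliberate: the downstream mixture model only needs approximate symmetry
of the healthy component, and a continuously optimized λ would track
contamination.

**Mixture deconvolution**: Gaussian mixtures with k = 1…4 components are
fitted on the transformed scale by EM (relative log-likelihood tolerance
1e-8, at most 1,000 iterations, 5 seeded restarts from quantile-spread
initializations, the first unjittered; the log-likelihood is asserted
non-decreasing each iteration). The BIC (−2·loglik + (3k−1)·log n) picks k.
k = 1 is the closed-form normal fit. EM on heavily overlapping components
converges sublinearly and may legitimately exhaust the iteration budget;
the best fit is then returned with `converged=False` and a warning —
truncation quality is insensitive to those final sub-1e-4 wiggles.

**Modes and antimodes** come from a Silverman-bandwidth Gaussian KDE
evaluated on a 512-point grid: interior local maxima are modes, interior
minima strictly between the outermost modes are antimodes, so the two
strictly interleave.

**Truncation** combines the mixture fit with the density scan. The
antimodes partition the axis into mode basins. The healthy basin is the
one carrying the greatest total mixture weight; its heaviest component is
recorded as the representative. All components in the healthy basin are
merged, because BIC routinely splits one platykurtic or skewed healthy
component into 2–3 overlapping Gaussians (the outlier fences truncate the
tails, and a truncated normal is fitted better by a small mixture) — using
a single component's responsibility there would collapse the window onto a
sliver of the healthy distribution. The truncation window is the
contiguous interval around the representative mean where the merged
cluster's posterior responsibility stays ≥ 0.5; a side where it never
drops below 0.5 ends at the data extreme, and a flanking antimode
overrides a responsibility boundary that lies beyond it. With well
separated components (each owning its mode) this reduces exactly to the
single-component responsibility rule, and with k = 1 the window is the
full data range. Window edges found by responsibility crossings are
refined by root finding (Brent) between grid points.

**Percentiles**: the RI is the central 95% of the raw values inside the
window, computed with the CLSI nonparametric rank convention r = p(n+1)
with linear interpolation (numpy's "weibull" quantile), requiring at least
120 in-window values (the CLSI minimum reference sample size).

**Confidence intervals**: seeded percentile bootstrap — 1,000 resamples of
the in-window values, both percentiles recomputed per resample, the
central 90% of each bootstrap distribution reported. Validated by
simulation: on clean N(0, 1) samples of n = 20,000 the 90% CIs cover the
true quantiles in ≈ 95% of replications (the acceptance suite requires
≥ 85% over 200 replications).

## HOMA-IR and units

HOMA-IR = glucose (mmol/L) × insulin (μU/mL) / 22.5. Glucose stored in
mg/dL is divided by 18.02 first. Two insulin conventions are exposed:
the WHO/ADA factor (1 μU/mL = 6.00 pmol/L, the default) and a legacy
reciprocal convention (pmol/L × 0.166 = μU/mL, i.e. 1 μU/mL = 6.024
pmol/L). They differ by the fixed ratio 6.00 × 0.166 = 0.996, which is
exactly why some published tables are reproducible only under one of the
two; reports state the active convention. Display rounding is 1 decimal
for converted analytes and 2 for HOMA-IR; internal math is full precision.

## Exclusion filtering

Thresholds are exclusion-side bounds (inclusion is the strict complement:
glucose 99 mg/dL retained, BMI 25.0 excluded, HDL-c exactly at the sex
minimum retained). Records missing any required field, or with an
unrecognized sex code, are excluded under `missing_data` rather than
imputed. Each exclusion is attributed to the first failing criterion in a
configurable order — the simplest accounting that conserves
`n_input = n_retained + Σ excluded`. Multi-visit subjects beyond the visit
limit are dropped entirely; otherwise the earliest visit is kept (by
`visit_date` when present, else input order), minimizing treatment-induced
drift.

## Partitioning

Sex-specific intervals are warranted when the Harris–Boyd statistic
z = |x̄₁ − x̄₂| / √(s₁²/n₁ + s₂²/n₂) exceeds z* = 3·√(n̄/120) with
n̄ = (n₁+n₂)/2, or when the SD ratio (larger/smaller) reaches 1.5. The
criterion assumes roughly Gaussian groups, so by default it is applied on
the symmetrized scale chosen by the transform-selection stage for the
pooled sample; a raw-scale mode exists. Mann-Whitney tests accompany the
descriptive summaries: at large n the sexes can differ significantly while
still failing the partitioning criterion — that distinction is the point.

## The synthetic cohort generator

The generator (`refrange.cohort`) emulates the structure of a routine LIS
extract. Defaults, chosen to mirror a plausible adult outpatient
population with a large female majority:

| Parameter | Default | Rationale |
|---|---|---|
| n_subjects | 20,000 | typical post-filter scale of an LIS study |
| female_fraction | 0.86 | observed female predominance in screening cohorts |
| healthy_fraction | 0.75 | 25% pathological contamination |
| healthy insulin (F) | lognormal, median 6.6, logsd 0.35 μU/mL | right-skewed, central 95% ≈ 3.3–13.1 |
| healthy insulin (M) | median 6.5, logsd 0.35 | slightly lower than women |
| pathological insulin | one component, median 16.5 (2.5×), logsd 0.45 | insulin-resistant subpopulation |
| glucose | N(89, 5²) mg/dL | normoglycemic range 70–99 |
| BMI | N(22.5, 1.8²) kg/m² | mostly inside [18.5, 25) |
| A1C | N(5.3, 0.18²) % | below the 5.7% threshold |
| Tg | lognormal(log 73, 0.35) mg/dL | right-skewed lipids |
| HDL-c | N(62, 10²) F / N(50, 9²) M mg/dL | sex-specific |
| shift multipliers | glucose 1.25, BMI 1.25, A1C 1.12, Tg 2.0, HDL 0.8 | full-severity shifts crossing every threshold |
| medication P(any) | 0.6 pathological / 0.05 healthy | flags correlate with disease |
| insulin–glucose ρ | 0.3 (healthy, shared latent) | HOMA-IR varies realistically |

Pathological members draw insulin from the pathological component; their
*severity* is `s = Φ(z)^0.5`, the concave ramp of the insulin z-score's
quantile, and every other analyte is shifted by `multiplier^s`. Severity
comonotone with insulin reflects that hyperinsulinemia and metabolic
comorbidity advance together, and the concave ramp encodes that
comorbidity appears early in insulin resistance. The consequence — by
design — is that the exclusion filters remove almost all severely affected
members while a mildly affected residue (a few percent of retained
records, with insulin overlapping the healthy range) survives: the
indirect method's working premise that filtering is strongly enriching but
imperfect. Flat multipliers would instead make survival essentially
impossible (every member would cross several thresholds jointly) and the
truncation stage would have nothing to do.

Exam counts are drawn from {1,…,4} with pathology-weighted probabilities
to exercise the visit-limit exclusion; heights are sex-specific truncated
normals; analytes are hard-resampled on any non-positive draw. Everything
derives from one seeded generator, so cohorts are byte-identical for a
fixed seed. `true_healthy_quantiles` returns the analytic lognormal
quantiles of the healthy component (for both sexes pooled, the mixture CDF
is inverted numerically), giving exact ground truth for recovery tests.

What the generator does **not** emulate: assay analytical error,
pre-analytical fasting violations, seasonal or age trends in the healthy
component (age is uniform and independent of analytes), race/ethnicity
structure, and free-text medication reporting. Passing recovery tests
therefore demonstrate that the statistical machinery isolates a dominant
lognormal component under threshold-correlated contamination — not that
any particular published interval is correct for a real population.

## Validation design and problem sizes

The test suite validates each stage against independent oracles:
closed-form lognormal quantiles (cross-checked by Monte Carlo at 10⁶
draws), analytic responsibility crossings for two known Gaussians,
scikit-learn's GaussianMixture as an independent EM implementation,
brute-force rank counts for Mann-Whitney, and hand-applied filter rules on
a packaged 12-record example. End-to-end recovery uses 10 cohorts of
20,000 subjects (25% contamination): the filtered pipeline must recover
the true healthy 2.5th/97.5th insulin percentiles within 5% (seed-suite
mean), while naive percentiles of the raw mixture overshoot the upper
bound by far more than 25%. Bootstrap coverage uses 200 replications at
n = 20,000; partitioning stability uses 100 cohorts of 2,000 with
identical sex parameters. These sizes keep the full suite's statistical
checks meaningful at desk scale.

## Known limitations

- **Flank-hugging contamination biases the bounds.** When the
  pathological component overlaps the healthy flank heavily (e.g. the
  unfiltered default mixture: 25% weight at a 2.5× median shift), the
  responsibility-0.5 boundary falls below the healthy 97.5th percentile
  and the truncated percentile underestimates it by ~10% regardless of how
  well EM fits. The exclusion filters are not optional preprocessing; the
  estimator is designed for the post-filter residue of contamination.
- **Tail trimming costs a few percent.** The adjusted-boxplot stage
  removes ≲ 1% of a clean right-skewed sample, which drags the
  outer percentiles of the remainder inward by ~2–4% at the defaults.
  This is the familiar bias-robustness trade of every outlier rule; the
  fence constants are config-exposed.
- **Percentile-bootstrap CIs are a stand-in.** The CI method is a seeded
  percentile bootstrap, labelled as such in reports, not a closed-form
  quantile CI; coverage is validated by simulation only for the clean
  large-n regime.
- **The truncation rule is one deterministic choice** among the many ways
  mixture output and density modes can be combined; alternatives (e.g.
  responsibility thresholds other than 0.5) are config-exposed but
  untested beyond the default.
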