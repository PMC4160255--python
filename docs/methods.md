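# Methods

This note records the statistical model behind `ewdclim`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Standardization

Each measurement series (ring width in file units, or earlywood density in
g/cm³) is divided by a deterministic growth curve fitted on a cambial-age
axis `t = 0, 1, …` counted from the first measured ring (no pith offsets
are modelled). The cascade is:

1. **Modified negative exponential** `y(t) = a·e^(−bt) + d`, fitted by
   Levenberg–Marquardt nonlinear least squares. Initialization: `a₀` =
   first-decade mean − last-decade mean (floored at a small positive
   value), `b₀ = 2/n`, `d₀` = last-decade mean; tolerances 1e-12, up to
   10⁴ function evaluations (tight, because exact parameter recovery on
   noiseless input is part of the test contract). The fit is accepted only
   if `a > 0`, `b > 0`, the curve is strictly positive over the whole
   span, and the decay is non-degenerate (`b·n ≥ 1e-3`; a slower decay is
   numerically a straight line and is handed to the next stage). No sign
   constraint is placed on `d` beyond curve positivity.
2. **Straight line**, accepted only with slope ≤ 0 *and* a strictly
   positive fit over the span — a non-positive divisor would make ratio
   indices undefined, so positivity is required here as a package design
   choice even though the classical rule mentions only the slope.
3. **Horizontal mean** of the non-missing values, always accepted.

Indices are ratios `value/curve` (dimensionless, mean ≈ 1 over the fitted
span). Dated missing rings are encoded as value 0, excluded from every fit,
and map to index 0. The cascade is deterministic: identical input always
selects the same curve.

Out of scope by design: spline/RCS/signal-free standardization and
autoregressive (residual) chronology variants — only the *standard*
chronology is produced.

## Chronology, Rbar and EPS

The site chronology is the per-year Tukey biweight location (tuning
constant c = 9, scale = median absolute deviation about the current
estimate, median start, convergence 1e-8 relative or 50 iterations; zero
MAD returns the median) over all index series covering that year.

Signal strength uses gliding windows: 30-year windows advanced by 15 years
(50% overlap). "Windows separated by 30 years" is ambiguous between
step = 30 and window = 30; the 50%-overlap reading is the dominant
convention and yields a continuous EPS trace for the truncation decision,
so it is the default, and both window and step are arguments. Within a
window, `rbar` is the mean of all pairwise Pearson correlations between
series sharing at least half the window there (within-tree core pairs
included — an average over *all* pairs); `N` is the mean number of series
present per year; `EPS = N·rbar/(N·rbar + 1 − rbar))`. Windows with fewer
than two series are flagged undefined; non-positive `rbar` reports EPS 0
with a low-signal flag rather than an error. Whether `N` should instead
count trees is an unresolved convention; core count is the default here.

Per-year values are taken from the window whose centre is nearest. The
reliable period starts at the earliest year from which, through the end:
EPS > 0.80 — or the documented override EPS ≥ 0.75 with ≥ 4 trees, which
codifies the practice of retaining a marginally low window when tree
coverage is adequate — and depth ≥ 4 trees and ≥ 6 cores. The per-window
decision trail is attached to the truncated chronology.

## Climate response

The monthly predictor window defaults to July of the year before growth
through September of the growth year (15 slots; sources describing this
window as "14 months" while naming those endpoints are treated as
miscounting — the endpoints govern).

* **Correlation function**: per-slot Pearson correlation; paired-year
  bootstrap (years resampled with replacement, rows kept intact), 95%
  percentile bounds, significance = interval excludes zero; t-based
  p-values are also reported but the bootstrap governs the flags.
  Default 1000 replicates, seed mandatory. Caveat: at n ≈ 56 the
  percentile bootstrap is slightly anti-conservative — its true type-I
  error is ≈ 0.065 rather than the nominal 0.05, because the bootstrap
  variance of a correlation is biased low in small samples. This is a
  property of the prescribed method, not of the implementation; treat
  marginal flags accordingly.
* **Response function**: principal-component regression. Predictors are
  standardized inside the operation (coefficients are per standard
  deviation of each month and invariant to affine rescaling); components
  of the correlation matrix with eigenvalue > 1 are retained (Kaiser
  rule; a cumulative-85% rule is available); the index is regressed on
  the retained scores and coefficients are mapped back to month space.
  The whole construction, including retention, is recomputed in every
  bootstrap replicate.
* **Partial correlation**: closed form
  `(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))`, p from t with n−3 df;
  verified in tests against the residual-regression route and an
  independent implementation.

## Calibration and verification

Simple OLS of the seasonal climate target (default: mean of May and June
maximum temperature) on the chronology index, requiring ≥ 20 common years.
Verification is leave-one-out (there is no room for a split-period design
in a ~56-year record): the LOO predictions use the exact closed form
`e_i/(1 − h_ii)`, identical to n refits. The battery:

* `RE = 1 − Σ(o−p)²/Σ(o−ō_cal)²` with `ō_cal` the calibration-period mean
  of the observations (LOO predictions against the full-calibration mean —
  with a single period the coefficient of efficiency coincides with RE and
  is reported as such).
* Sign test on departures from the calibration mean (not first
  differences, so counts can sum to the full calibration length); exact
  zeros enter neither count; two-sided binomial p.
* Product-means t: departure products split by sign; t contrasts the mean
  positive product with the mean magnitude of negative products, with
  ddof = 1 standard deviations, Welch-style standard error and degrees of
  freedom. An all-agreement split (no negative products) is reported as a
  flag, not an error; zero variance in both groups is an error.

## Reconstruction

Transfer applied over the reliable chronology span; mean and σ (ddof = 1)
computed over the full reconstructed span. Warm years are > mean + 1σ,
cold < mean − 1σ; percentages are rounded to whole percent with the normal
share reported as the complement so the three always total 100.

Decadal structure: the "10-year low-pass" is realized as a second-order
Butterworth designed at 0.1 cycles/yr and applied forward–backward
(zero-phase, so filtered extrema keep their calendar dates), with
odd-reflection padding, which transmits straight lines unchanged. The
amplitude gain of the doubled filter is `1/(1 + (f/f_c)⁴)`: ≈ 0.996 at a
40-yr period and ≈ 0.025 at 4 yr. Warm/cold periods are maximal runs of
the filtered curve strictly above/below the full-reconstruction mean of at
least 5 years (the shortest period such studies report); shorter runs are
emitted as "unclassified" so every year is covered exactly once.

## Field diagnostics

Correlation maps remove each side's OLS linear-in-year trend over the
common years of each cell before correlating; cells with fewer than 20
common years are masked. Composites select the k highest/lowest series
years (`k = round(n/10)` half-up for "decile", or explicit, e.g. 12), with
ties broken toward the earlier year, and average field anomalies relative
to a configurable base period (default: all common years). Vector fields
are two scalar fields composited independently.

## The synthetic generator

The generator emulates the study conditions the analysis assumes, with all
truth recorded:

* **Climate.** Monthly mean temperature follows a two-harmonic seasonal
  cycle through January −2.2 °C, July 22.8 °C and annual mean 11.0 °C;
  maximum temperature adds a constant offset of 6.0623 °C, placing the
  May–June climatology at 25.6 °C. Monthly anomalies are a standardized
  AR(1) chain (φ = 0.3) scaled by 0.8 °C — the monthly σ implied by a
  reconstruction σ of ~0.4 °C at r² ≈ 0.4. Precipitation multiplies
  hand-set monthly normals (July max 92.3 mm, December min 3.2 mm, annual
  total 521.0 mm, June–September share 64.8%) by a mean-corrected
  exponentiated AR(1) anomaly (log-σ 0.35), keeping values non-negative
  without clipping. Temperature and precipitation chains are independent
  (see limitations).
* **Trees.** 25 trees carry 63 cores (alternating 3 and 2 per tree); four
  trees reach the 1666 span start (10 cores), the rest enter on a
  staggered schedule to 1895, so sample depth decays back in time exactly
  as the reliability rule expects. Each core gets a modified negative
  exponential curve (a ∈ [0.10, 0.25], b ∈ [0.01, 0.04] yr⁻¹,
  d ∈ [0.40, 0.50] g/cm³, with small within-tree jitter).
* **Signal.** The latent index is
  `1 + γ_T·z(T_MJ) + γ_P·z(P_MJ) + ε_tree + ε_core`, floored at 0.05, and
  the measurement is `curve × index` — multiplicative, so ratio detrending
  is the generator's correct inverse. Defaults γ_T = 0.14, γ_P = −0.168,
  σ_tree = 0.16, σ_core = 0.18 follow from three targets solved jointly:
  population chronology–temperature correlation
  `γ_T/√(γ_T² + γ_P² + σ_eff²) ≈ 0.63` (σ_eff² = σ_tree²/25 + σ_core²/63),
  between-tree common-variance fraction
  `(γ_T² + γ_P²)/(γ_T² + γ_P² + σ_tree² + σ_core²) ≈ 0.45` (so EPS > 0.8
  already at 6 cores), and a total index σ small enough (≈ 0.33) that the
  positivity floor is touched with negligible probability. The truth
  bundle stores the true May–June series, the population transfer slope
  `β = γ_T·s_T/(γ_T² + γ_P² + σ_eff²)`, the γs, noise tiers, curve
  parameters and the common-variance fraction.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: the observed negative dependence between
spring temperature and precipitation (kept independent so each signal is
separately identifiable; one visible consequence is that the synthetic
partial correlation of temperature given precipitation *exceeds* the raw
correlation, whereas observed records show the reverse); dating error and
missing-ring misassignment; divergence or any non-stationarity of the
climate–growth relation; sub-annual density structure; and spatial
autocorrelation between trees.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
The test suite exercises the full pipeline at the study's native size
(63 cores × 343 years; a single end-to-end run takes well under a second),
uses 100 replicate synthetic studies for the parameter-recovery check,
200 × 15 null slots for the bootstrap specificity check, and 6–10 replicate
seeds per point for generator-target checks; these sizes give the binomial
or sampling bands quoted in the tests their stated power. The acceptance
script reports statistics from one full study at the native size.

## Known limitations

* RWL output writes integer values (the format has no fractional field);
  density data should travel through the CSV interchange.
* EPS uses core count for N by default; tree-count EPS is available but
  not the default, and the truncation rule's override is a codified
  convention, not a statistical test.
* The percentile bootstrap's small-sample anti-conservatism noted above.
* Reconstruction uncertainty (prediction intervals) is not produced.
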