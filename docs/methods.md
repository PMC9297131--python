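# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `diurnality`, at the level of detail a maintainer or
reviewer needs to judge what the package does and does not establish.

## Data model

The unit of analysis is one search term's hourly relative-search-volume
(RSV) series over a study year. Raw Trends-style input is long CSV — one row
per (term, location, UTC timestamp, replicate, rsv) — with integer RSV in
0–100 per download. The pipeline mirrors the standard acquisition protocol
for such data: each location is downloaded more than once (RSV is a sampled,
non-replayable quantity), replicates are averaged pointwise, each location's
series is converted to its local civil time, and locations are pooled.

Pooling is by pointwise mean on the **local-clock grid**: each state's 06:00
is aligned with every other state's 06:00, which is the alignment that makes
pooled diurnal harmonics meaningful. DST artifacts are retained (the doubled
fall-back hour is averaged, the skipped spring hour is a flagged gap); they
amount to two hours per year and are immaterial to the harmonic fit, which
runs on observed rows only. Seasons are meteorological (DJF/MAM/JJA/SON) on
local dates. Missing hours are never imputed.

## Regression model

With x = hours elapsed since local midnight on Jan 1 of the study year,
t = local clock hour, ω = 2π/24:

* **Trend**: third-order orthogonal polynomials in elapsed days x/24,
  orthonormalized on the observed rows by QR of the centered/scaled
  Vandermonde matrix. The transform is stored so the basis can be evaluated
  at arbitrary times (the study midpoint, for curve construction). The
  continuous covariate x/24 is used rather than integer day-of-year; over a
  year the difference is negligible and the continuous version is smooth.
* **Harmonics**: sin(nωt), cos(nωt) for n = 1..4, built separately for
  weekday and weekend rows, plus one 0/1 weekend-level column. The level
  column matters: with separate harmonic *shapes* but a common mean, the
  weekend amplitude-to-mean ratio would not be identifiable from the fit.
* **Nuisance indicators**: for each width k in the ladder (default
  {8, 16, 32, 64, 128, 168} hours; presets {7, 14, 28, 56, 112, 168} and
  {9, 18, 36, 72, 144, 168} ship for sensitivity analysis), windows
  m = 0, 1, ... tile the axis; column (k, m) is 1 on hours
  km ≤ x ≤ k(m+1)−1. The truncated final window of each width is kept so
  each width's columns exactly partition the axis.

## Outlier selection (partially penalized LASSO)

Isolated surges (news events, epidemics) bias harmonic coefficients, so the
indicator ladder is offered to a LASSO that penalizes **only** the indicator
block — the intercept, trend, and harmonics are never shrunk, since the
harmonic coefficients are the quantities of interest. The partially
penalized problem is solved exactly by profiling: for fixed indicator
coefficients b, the optimal unpenalized coefficients are OLS of (y − Nb) on
the unpenalized block U, so the joint problem reduces to a LASSO of the
U-residualized response on the U-residualized indicators. The reduced
problem is solved with scikit-learn's LARS-LASSO path from a Gram matrix
computed in closed form, N'N − (U'N)'(U'U)⁻¹(U'N), keeping the sparse 0/1
block sparse. Indicator columns are standardized to unit (residualized) norm
inside the LASSO only — wide windows would otherwise be under-penalized —
and reported on the original 0/1 scale after the OLS refit.

The penalty is chosen by 10-fold cross-validation on a 100-point geometric
grid spanning three decades below the critical penalty, taking the sparsest
value within one standard error of the CV minimum (the "1se" rule; "min" is
available). Folds are a **seeded random partition of observations**, not
contiguous blocks: an interval indicator predicts only its own window, so
with contiguous folds the window sits wholly inside one held-out fold — the
training data can then never learn it and CV would always return the empty
model. Random folds place ~90% of a surge's hours in training, which is what
lets cross-validation credit the indicator. (Random folds slightly
underestimate prediction error under serial correlation; for selecting
strong localized outliers this bias is immaterial, and inference is
delegated to the block bootstrap regardless.) Before the path is run, the
candidate set is screened to the ~480 columns with the largest residualized
correlations — far above the path-length cap of 60 — which is lossless in
practice for localized-outlier designs and keeps the per-fold Gram small.

Degenerate cases: if the residualized correlations are numerically zero
(noiseless data fully explained by the unpenalized block), selection
short-circuits to the empty set. Exactly duplicated selected columns (a
truncated final window can coincide across widths) are deduplicated keeping
the narrowest width, then the earliest window — the most local explanation.
A rank-deficient post-selection design falls back to minimum-norm OLS with a
warning.

The final fit is plain OLS on [intercept | trend | harmonics | weekend level
| selected indicators]. The **filtered series** is the observation minus the
fitted indicator contribution; trend and harmonics are retained. For plots,
the default input is additionally detrended with the mean level restored
(raw-filtered is a flag).

## Circular summaries

Each day type's fitted curve is evaluated on a 1-minute grid over [0, 24) —
peak times are reported to the minute — as intercept + trend at the study
midpoint (+ weekend level) + the day type's eight trigonometric terms, making
it a pure function of clock time.

* **Circular median**: the curve minimum is subtracted and the remainder
  treated as a nonnegative weight density on the 24-h circle; the median is
  the grid point minimizing the weighted mean arc distance (shorter-arc
  metric), ties broken by earliest clock time. Min-subtraction makes the
  statistic baseline-invariant and peak-seeking: for a unimodal curve it
  sits at the peak. A constant curve has no defined median and raises.
* **Amplitude-to-mean ratio**: (max − min)/mean on the grid; requires a
  positive mean.
* **AMR contrast**: (weekend amplitude − weekday amplitude) / mean of the
  two curve means; negative ⇒ stronger weekday cyclicity.
* Clock-time differences use the shorter arc (≤ 12 h) and are bucketed into
  2-hour bands "0-2" … "10-12" for tabulation.
* Polar-plot normalization divides each group's 24 hourly means by the
  minimum hour, so the quietest hour plots at radius 1.0.

## Bootstrap inference

A residual-based circular moving-block bootstrap: ceil(n/20) block starts
are drawn uniformly (blocks of 20 hours, wrapping at the series end),
concatenated, truncated to n, and the resampled residuals are added back to
the outlier-free fitted values. Resampling residuals rather than raw data
preserves the deterministic design (weekday/weekend structure, trend), which
whole-series resampling would scramble; 20-hour blocks span the short-range
serial dependence of hourly search noise while staying below the 24-hour
cycle. Each replicate is refitted by OLS with the indicator support frozen
at the original selection — per-replicate re-selection is unstable and
orders of magnitude more costly, and the summaries of interest live in the
harmonic block. Refits are vectorized through one precomputed pseudoinverse.

Reported per statistic: percentile CIs (default 95%, 1000 replicates) for
the AMRs and the contrast; arc-based percentile CIs for circular medians
(percentiles of signed shorter-arc deviations from the point estimate,
mapped back to the clock); and per day type a diurnality P value — the Wald
statistic of the eight harmonic coefficients under the bootstrap covariance,
referred to its χ²₈ limit, with the conventional significance rule P < .001.
A degenerate bootstrap distribution (all replicates identical) is flagged
and collapses the CIs to the point estimate.

All randomness flows from (seed, replicate); runs are bit-reproducible, and
the pipeline derives its simulation, CV, and bootstrap seeds from one base
seed via `numpy` seed sequences (recorded in the run manifest).

## Synthetic data

The generator emulates the structure of combined Trends data: a year
(8760 h) of hourly values anchored to the real 2018 calendar, mean curve
baseline + cubic trend (parameterized in elapsed years so order-1
coefficients move the level by order-1 RSV units over the year) + day-type
harmonics (orders 1–4, amplitude/phase form), additive boxcar surges,
additive Gaussian noise clipped at zero, and an optional per-week rescaling
to max 100 with optional integerization, mimicking Trends' independent
scaling of each weekly request window. Defaults describe a plausible
eye-condition term: baseline 50, drift of a few RSV units, weekday rhythm of
amplitude 15 peaking 05:00 with a second harmonic sharpening the peak,
weekend rhythm of amplitude 12 peaking 07:00, noise SD 5 (~10% of baseline,
the scale of replicate-to-replicate scatter in Trends downloads).

Ground-truth summaries are computed by running the package's own circular
operations on the noiseless day-type curves, so truth and estimate share one
set of numerical conventions rather than duplicating approximations.

What the generator does **not** emulate: Google's sampling algorithm and
query-share denominator, integer quantization (unless per-week rescaling
with integerization is enabled), media-driven correlated bursts beyond
boxcar shape, and missing-data patterns. Passing recovery tests therefore
establishes correctness of the estimation machinery under the stated
generative model, not robustness to every artifact of real Trends data.

## Simulation study sizes

The shipped calibration studies use: exact-recovery and filter-efficacy runs
at the full year length n = 8760 (50 noise seeds for the filter study);
bootstrap calibration with 300 coverage replicates and 400 null replicates
at 200 bootstrap resamples each (the per-analysis default remains 1000
resamples); and 100-curve oracle checks for the circular median. These sizes
give Monte-Carlo standard errors comfortably inside the tolerances they are
checked against (e.g. ±1.3% on a 95% coverage estimate at 300 replicates).

## Known limitations

* CV-based selection can absorb a genuine rhythm change into indicators if a
  surge repeats periodically; the filter targets *localized* departures.
* The χ²₈ reference for the Wald statistic ignores the finite number of
  bootstrap replicates; with 200 replicates the test is very slightly
  liberal in the far tail (empirically still below nominal at α = .001).
* The circular median is a peak summary only for approximately unimodal
  curves; for strongly bimodal rhythms it reports the weighted compromise.
* Weekly rescaling (when enabled) distorts the level structure the trend
  block expects; the analysis of rescaled data estimates rhythms of the
  rescaled series, which is what Trends actually delivers.
* Live Trends fetching is out of scope; the package analyzes data you
  provide in the documented CSV layout.
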