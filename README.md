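# diurnality

Diurnal and day-of-week analysis of hourly web-search time series.

Public web-search interest in health conditions — relative search volume
(RSV) as returned hourly by Google Trends — often follows daily rhythms:
searches for an acutely symptomatic condition may spike every morning, while
searches about elective procedures cluster in working hours. `diurnality` is
a toolkit for epidemiologists and health-informatics researchers who want to
estimate and compare such rhythms from a year of hourly RSV data: when does
search interest for a term peak, how strong is its daily cycle, and does the
weekend pattern differ from the weekday pattern?

## The model

For one search term, the hourly series y(x) (x = hours elapsed since local
midnight, Jan 1 of the study year) is fitted by a Serfling-type harmonic
regression

    y(x) = β₀ + trend(x/24) + Σₙ₌₁⁴ [ aₙᵈ sin(nωt) + bₙᵈ cos(nωt) ]
           + γ·1{weekend} + Σ_{(k,m)∈S} c_{k,m}·1{km ≤ x < k(m+1)} + ε(x),

with ω = 2π/24, t the local clock hour, trend a third-order orthogonal
polynomial in elapsed days, and separate harmonic coefficients (aₙᵈ, bₙᵈ) for
weekdays and weekend days d plus a free weekend level γ. The last sum is an
outlier filter: a ladder of 0/1 interval indicators of widths
k ∈ {8, 16, 32, 64, 128, 168} hours tiles the year, and a cross-validated
LASSO — penalizing only the indicator block — selects the sparse set S of
windows needed to absorb epidemics, news-driven surges, and other localized
departures. The final coefficients are ordinary least squares on the
unpenalized blocks plus the selected indicators; subtracting the fitted
indicator contribution yields the outlier-filtered series.

From the fitted coefficients each day type gets a 24-hour mean curve, reduced
to three headline statistics:

* **circular median time** — the clock time minimizing the weighted mean arc
  distance on the 24-h circle (weights = min-subtracted curve): the peak
  time for a unimodal rhythm;
* **amplitude-to-mean ratio (AMR)** — (peak − trough)/mean, the unitless
  strength of the cycle;
* **AMR contrast** — (weekend amplitude − weekday amplitude) divided by the
  average of the two means; negative means stronger weekday cyclicity.

Standard errors, percentile CIs, and a diurnality P value (Wald test on the
eight harmonic coefficients of a day type, bootstrap covariance, χ²₈
reference; significance at P < .001) come from a residual-based circular
moving-block bootstrap with 20-hour blocks.

A synthetic-data module generates Trends-like hourly series with known trend,
day-type harmonics, noise, injected boxcar surges, and optional per-week
0–100 rescaling, so every pipeline stage is testable against ground truth.

## Worked example

Simulate a year of hourly data for a "pink eye"-like term — weekday rhythm
peaking 05:00, weaker weekend rhythm peaking 07:00, noise SD 5, plus a
+60-RSV surge lasting 8 hours — then fit and summarize:

```python
from diurnality import (SyntheticSpec, Surge, simulate_series,
                        DiurnalHarmonicRegression, BootstrapConfig,
                        bootstrap_summaries, format_clock)

spec = SyntheticSpec(noise_sd=5.0, outliers=(Surge(800, 8, 60.0),), seed=1)
series, truth = simulate_series(spec, term="pink eye")

est = DiurnalHarmonicRegression().fit(series)
print("selected outlier windows:", est.selected_columns_)

summary = bootstrap_summaries(est.model_,
                              BootstrapConfig(n_reps=1000, seed=2),
                              term="pink eye")
for dt in ("weekday", "weekend"):
    lo, hi = summary.ci[f"median_{dt}"]
    print(f"{dt}: median {format_clock(summary.circular_median[dt])} "
          f"(95% CI {format_clock(lo)}-{format_clock(hi)}), "
          f"AMR {summary.amr[dt]:.3f}, "
          f"P(diurnality) {summary.p_value[f'diurnality_{dt}']:.2g}")
print(f"AMR contrast (weekend - weekday): {summary.amr_contrast:.3f}")
```

Output:

```
selected outlier windows: [(8, 100)]
weekday: median 04:59 (95% CI 04:57-05:02), AMR 0.649, P(diurnality) 0
weekend: median 06:57 (95% CI 06:52-07:03), AMR 0.451, P(diurnality) 0
AMR contrast (weekend - weekday): -0.198
```

The filter finds exactly the injected surge window (width 8, window 100 =
hours 800–807); the estimated peak times sit within a few minutes of the
generative truth (05:00 and 07:00); both rhythms are overwhelmingly
significant; and the negative contrast reports the stronger weekday cycle.

The same analysis runs from the shell against a YAML config (CSV input or a
synthetic scenario), producing a summary table, polar plots, and a manifest:

```sh
diurnality run-all config.yaml
diurnality sensitivity config.yaml   # compare indicator width ladders
```

## Layout

| module | contents |
| --- | --- |
| `diurnality.io` | `HourlySeries`, CSV I/O, time zones, replicate/state pooling |
| `diurnality.simulate` | `SyntheticSpec`, Trends-like generator with ground truth |
| `diurnality.basis` | trend/harmonic/indicator design blocks, width presets |
| `diurnality.model` | `DiurnalHarmonicRegression`, LASSO selection, OLS, filtering |
| `diurnality.summaries` | circular median, AMR, contrast, bands, normalization |
| `diurnality.bootstrap` | block bootstrap, CIs, diurnality P values |
| `diurnality.viz` | normalized 24-h polar plots (overall / weekday / season) |
| `diurnality.pipeline`, `diurnality.cli` | YAML-configured end-to-end runs |

See `docs/methods.md` for the statistical details and design decisions.
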