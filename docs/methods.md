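# Methods

This note documents the models, estimators, numerical choices, and
known limitations of `vegres`, in the order the pipeline applies them.

## Linearized dynamics and the two theoretical restoring-rate estimators

Vegetation anomalies around a stable state are modelled as an
Ornstein–Uhlenbeck (OU) process dx̄ = λx̄dt + σdW with restoring rate
λ < 0 (units 1/yr). Sign convention throughout: λ (and the empirical
recovery rate r) are negative for stable, recovering systems; values
closer to zero mean slower recovery and lower resilience.

Sampling at step Δt gives an AR(1) process with coefficient e^{λΔt};
the stationary variance is −σ²/(2λ) and the lag-n autocorrelation
e^{nλΔt} (only n = 1 is used). `estimate_ac1` uses the Pearson
correlation of the series with its one-step lag over the full series,
pairwise-complete (missing samples are never interpolated at this
stage). `lambda_from_ac1` inverts λ = ln(AC1)/Δt for AC1 ∈ (0, 1);
AC1 ≥ 1 is flagged non-stationary and AC1 ≤ 0 out-of-model rather than
silently converted.

σ is not independently observable from a single series, so the
variance route substitutes the AR(1) innovation variance
σ̂²_ε = Var·(1 − AC1²) for σ²Δt, giving the discrete estimator
λ̂_var = −σ̂²_ε/(2·Var·Δt) = −(1 − AC1²)/(2Δt). An exact inversion
λ = −σ²/(2·Var) is available when σ² is supplied. The discrete
estimator equals the AC1 route in the Δt → 0 limit; at Δt = 1/24 yr it
is biased toward zero by a factor (1 − e^{2λΔt})/(−2λΔt) — about 8% at
λ = −2/yr, 12% at −3/yr, 27% at −8/yr. The two estimators' rank
ordering is essentially identical (rank correlation > 0.99 in
simulation), which is what the relationship analysis depends on.
Estimates are always computed over the full series, never in sliding
windows; temporal trends in resilience are out of scope.

All resilience estimates are reported in 1/yr using Δt = 1/24 yr
(24 samples per year, "bi-weekly" in the loose remote-sensing sense).
Time is carried as decimal years on an exact 1/24-yr grid; no calendar
arithmetic is performed anywhere.

## Empirical recovery rate

The detection chain on a residual series is: (1) ordinary
least-squares slopes in an 18-sample (9-month) moving window, assigned
to window centres; (2) a per-pixel threshold at the 99th percentile of
the magnitudes of the *negative* slopes (only drops are retained
downstream; a two-sided variant is configurable); contiguous
above-threshold runs form candidate regions and the steepest slope in
each region (earliest on ties) labels the disturbance; (3) validation
windows of 24 samples (1 yr) immediately before and after the region's
sample footprint, the footprint itself excluded: the candidate must
show a mean drop and pass a two-sample Kolmogorov–Smirnov test at
α = 0.05 (window lengths and α configurable; they are package
defaults, not values inherited from any reference analysis); (4) the
post-disturbance minimum is searched within 12 samples (6 months) of
the labelled peak, and the following 5 years are fitted with
x(t) = x₀e^{rt} by nonlinear least squares, seeded by a log-linear
regression on sign-consistent points, with x₀ free rather than pinned
to the minimum. Fits require ≥ 50% of the window present, no other
detected peak inside the window (compound events are rejected), and
R² ≥ 0.5 (configurable; chosen as a package default).

Operating characteristics measured in simulation (OU noise, λ = −2/yr):
recall ≈ 0.9 for injected drops of 5× the residual standard deviation;
with 8× drops the chain retains ≈ 85% of events and the median fitted
r is within a few percent of the injected −2/yr; noise-free fits are
exact to machine precision. On i.i.d. stationary null series the
drop + KS chain retains ≈ 1% of candidates, well under the 2α bound.
The i.i.d. null is the appropriate reference for the KS test's nominal
level, which assumes independent samples; on strongly autocorrelated
null series the KS p-values are anti-conservative (a known limitation
of the filter chain, not corrected here). A second selection property
worth knowing: events on *fast*-recovering pixels are preferentially
rejected by the KS filter, because one year after the transition the
series has already relaxed — the accepted-event sample is biased
toward large, slowly-recovering perturbations.

## Preprocessing

Despiking is a Hampel-style operator: a point deviating from its
7-sample running median by more than k = 4 scaled MADs
(1.4826·MAD ≈ σ) is replaced by that median and flagged. This is a
generic stand-in for sensor-specific contamination screening; it never
alters unflagged points.

Bi-weekly aggregation takes medians over half-open bins of width
1/24 yr anchored at the first timestamp; empty bins are missing.

Seasonality and trend are removed with STL (seasonal-trend
decomposition by loess): period 24, trend smoother 47 samples (just
under 2 yr), low-pass 25, robust fitting enabled. The seasonal
smoother, unspecified by the usual parameter citations, is set very
stiff (121, i.e. effectively a near-periodic seasonal component),
because a flexible seasonal loess absorbs residual variance the
resilience estimators need. Gaps of ≤ 4 samples are linearly
interpolated before decomposition; longer gaps are interpolated for
the fit but restored to missing in the residual; pixels missing > 20%
of points are dropped. Only the residual (observed − seasonal − trend)
is analysed.

**Known, quantified distortion.** Any ~2-yr detrending removes
low-frequency power. For an OU process with AC1 = 0.9 at Δt = 1/24 yr
(correlation time ≈ 0.4 yr, half its spectral power at periods
> 2.5 yr) the decomposition removes 50–65% of the variance and lowers
the residual AC1 by ≈ 0.10–0.13; even white noise acquires AC1 ≈ −0.04
from smoother subtraction. R's reference `stl` shows the same numbers,
so this is inherent to the prescribed parameters, not an
implementation artifact. Consequences: post-decomposition λ̂ is biased
toward faster rates, increasingly so for slow (λ → 0⁻) pixels, but the
monotone ordering of pixels by λ — which the binned Kendall-Tau
analysis uses — is preserved. White-noise variance passes through
within ~10%.

Land-cover masking keeps a pixel iff its IGBP-style class is in the
configured natural-vegetation set (forests, shrublands, savannas,
grasslands, wetlands by default; anthropogenic and non-vegetated
classes excluded) and identical across every year of the masking
period.

## Water predictors

Aridity is PET/MAP, so higher = drier and > 1 marks water deficit; a
helper converts the common MAP/PET orientation. The Walsh–Lawler
seasonality index is computed from long-term mean monthly totals
(climatological form; a mean-of-per-year variant is available), with
analytic range [0, 11/6]. Inter-annual variability is the sample
(n−1) standard deviation of calendar-year sums, normalized by MAP by
default — the normalized form is scale-invariant, while the raw form
scales linearly with MAP. The same operators serve for soil-moisture
series; there is no separate code path. A robustness mask keeps pixels
whose MAP lies in a per-class closed percentile band (default 40–60th,
inverted-CDF percentiles so the all-equal degenerate class keeps every
pixel).

## Binning and significance testing

For each (land cover, predictor, metric) triple: fixed-width bins over
the predictor's 1st–99th percentile range; bins with ≥ 50 members are
eligible; a relationship is reportable only with ≥ 10 eligible bins
and ≥ 1000 points in the class — classes and relationships failing the
rules are emitted with a reason code, not dropped silently. The
median line's tie-aware Kendall tau-b is computed against bin centres
(equivalent to bin indices for monotone edges). The Monte-Carlo
surrogate draws one member per eligible bin, 1000 iterations, one
seeded generator per relationship with the seed recorded. Because
medians smooth bin-to-bin fluctuations, |tau| of the median line
dominates the surrogate median in ≥ 95% of simulated runs; the
fraction of surrogates sharing the median line's sign is reported.

The default bin count is 14 with a sensitivity sweep over (12, 14, 16).
These were chosen by constraint at the demo scale (~1000 points per
class): expected membership ≈ 70 per bin keeps the 50-member rule
satisfied with sampling headroom while the total bin count exceeds the
10-eligible-bin floor; a 10-bin sweep would need literally every bin
to reach 50 members and is structurally fragile for skewed predictors.

## Synthetic landscape (what it does and does not emulate)

The generator encodes the statistical structure the analysis assumes,
with ground truth for validation:

- **Vegetation**: exact AR(1) sampling of the OU process (coefficient
  e^{λΔt}, innovation variance −σ²/(2λ)(1−e^{2λΔt}), stationary
  start), so the discrete sample has exactly the continuous process's
  variance and AC1 — no discretization bias enters the acceptance
  checks. On top: a single sinusoidal seasonal cycle (matching the
  period-24 decomposition), a linear trend, and optional injected
  perturbations that are literal realizations of the recovery model
  (instantaneous drop, exponential relaxation at a prescribed rate).
- **Precipitation**: annual totals are MAP times a unit-mean gamma
  factor with standard deviation equal to the target inter-annual CV
  (gamma because precipitation is non-negative, avoiding truncation),
  split across months by a von-Mises-style unimodal weight profile
  whose concentration sets the seasonality index, with small
  multiplicative within-month noise (CV 0.05).
- **Landscape**: pixels in land-cover classes with uniform per-class
  ranges of aridity, inter-annual CV, rainfall concentration, residual
  amplitude, seasonal amplitude and trend; λ_true is a clipped linear
  function of aridity and inter-annual CV with positive slopes, so
  drier and more variable pixels are constructed to be less resilient
  — the qualitative relationship the pipeline must recover, encoded as
  truth. About 35% of pixels receive one injected perturbation with
  amplitude 8× the residual standard deviation and recovery rate equal
  to the pixel's λ (theory: r = λ).
- **Demo scale**: 2 classes × 1000 pixels, 30 yr at 24 samples/yr —
  chosen so each class clears the 1000-point reportability rule while
  a full run completes in a few minutes on one CPU.

Not emulated: geographic structure (no projections, spatial
autocorrelation or coastlines), multi-sensor merging artifacts,
non-sinusoidal or drifting phenology, correlated vegetation-rainfall
anomalies at sub-annual scale, and real perturbation
amplitude/frequency distributions (the injection defaults are free
parameters, not calibrated values). Passing tests therefore
demonstrate that the estimators and the filter chain recover known
structure of this idealized data-generating process — not that the
method is unbiased on real satellite archives.

## Numerical and degenerate-input choices

- Zero-variance or too-short residual series yield flagged NaNs, not
  exceptions; λ inversions outside their domain are flagged the same
  way.
- Percentiles: relationship bin edges use numpy's default linear
  interpolation; the MAP robustness band uses inverted-CDF percentiles
  with a closed interval (exact enumeration on distinct values; keeps
  everything for an all-equal class).
- Kendall tau is scipy's tie-aware tau-b with two-sided p-values.
- Recovery-fit ties: the steepest-slope peak takes the earliest index;
  the surrogate draw orders points by bin centre, one pair per bin.
- Randomness: `numpy.random.default_rng` seeded per pixel via
  `SeedSequence.spawn`; identical seeds give byte-identical pipeline
  tables.
- Cubes are NetCDF3 via xarray's scipy engine; tables are CSV; every
  run directory contains the resolved configuration and a log with
  filter counts at each stage.

## Limitations

- The STL distortion quantified above means absolute post-pipeline λ̂
  values are compressed relative to truth; comparisons should be read
  ordinally.
- The KS validation inherits the i.i.d. assumption; its level is
  nominal only against serially-independent nulls.
- No spatial autocorrelation correction is applied in the significance
  tests (pixels are treated as exchangeable within a class).
- The empirical-recovery sample is selection-biased toward large, slow
  recoveries, so empirical and theory-based λ are best compared via
  their relationships to predictors rather than pixel-by-pixel.
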