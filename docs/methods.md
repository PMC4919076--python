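# Methods

This note documents the models, the estimation machinery, the synthetic
data, and the numerical and design choices behind `flyway`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Movement model and assumptions

Between consecutive GPS fixes the animal is assumed to follow a Brownian
bridge: conditioned on the two fixes, its position at interior time $t$ is
circular bivariate normal with mean on the chord and per-coordinate
variance

$$\sigma^2(t) = T\,\alpha(1-\alpha)\,\sigma^2_m
  + (1-\alpha)^2\,\delta_i^2 + \alpha^2\,\delta_j^2,$$

$\alpha = (t-t_i)/T$, $T = t_j - t_i$. The motion variance $\sigma^2_m$
(m²/s) measures how far the animal may stray from the straight-line
interpolation; $\delta$ is the GPS location-error SD. Assumptions worth
stating plainly:

- Movement is isotropic and Gaussian between fixes; real flight is
  directionally persistent within an hour, so $\sigma^2_m$ is an effective,
  not mechanistic, diffusivity.
- Location errors are independent, isotropic, and known (manufacturer
  spec); altitude is ignored — the UD is strictly two-dimensional.
- Coordinates are planar meters in an equal-area projection, so summing
  cells gives honest areas. The package performs no geodesy.

## Motion-variance estimation

$\sigma^2_m$ is estimated by **leave-one-out likelihood**: alternating
fixes (the 2nd, 4th, … of a window) are deleted and each deleted fix is
treated as an observation of the bridge spanned by its two retained
neighbors, with the deleted fix's own error variance $\delta^2$ added to
the bridge variance (the left-out point is itself a noisy observation;
omitting this inflates $\hat\sigma^2_m$ at short intervals). The negative
log likelihood is minimized over a log-spaced grid ($10^{-4}$–$10^4$
m²/s, 200 points) followed by bounded Brent refinement within the
bracketing grid interval. A single parabolic-interpolation step was tried
first and left up to ~2 % error depending on where the optimum fell
between grid points; Brent makes the estimate accurate to the stated 1 %
tolerance of the closed-form test case (60 m out-and-back in 3600 s
⇒ $\hat\sigma^2_m = 60^2/1800 = 2.0$ m²/s exactly).

Degenerate inputs: all-identical positions with zero error return 0 with a
warning; stationary-but-noisy fixes drive the estimate to the bottom of
the search grid (tested: median ≤ 10⁻³ m²/s for a perched bird with 18 m
noise).

### Dynamic (windowed) estimation

A window of 17 fixes slides along the segment one fix at a time — 17
matches the maximum number of fixes the duty cycle can deliver per day
(hourly 06:00–19:00 plus midnight). Within each window a single-variance
model competes against one-breakpoint models by
$\mathrm{BIC} = 2\,\mathrm{NLL} + k \ln n_{\mathrm{loo}}$, where
$n_{\mathrm{loo}}$ is the number of left-out fixes in the window (8 for a
17-fix window). Three choices here were genuinely open and were settled by
Monte-Carlo measurement (20-seed experiments, reproduced in the test
suite):

- **Candidate breakpoints sit at even local offsets only**, so the break
  fix is a retained fix. The two sides' leave-one-out sets then partition
  the full window's set exactly and the models are compared on identical
  observations. Allowing odd offsets compares likelihoods over different
  observation sets and selects a breakpoint in essentially every window of
  a constant-variance track. Both sides must keep at least `margin` (7)
  fixes, giving candidates {6, 8, 10} for the default window.
- **The breakpoint model is charged k = 3** (two variances plus the
  estimated break location), the standard change-point BIC counting. With
  k = 2 the best-of-three-candidates search selects a spurious breakpoint
  in ~30 % of constant-variance windows; with k = 3 this falls to ~11 %
  while a 25-fold variance jump is still localized reliably.
- **Profile assembly**: the winning model assigns its variance(s) to the
  window's non-margin intervals; each interval's final value is the mean
  over all windows that assigned to it, and never-assigned edge intervals
  inherit the nearest assigned value. With one window per ~2 interior
  intervals, each interval averages ~2 fits of ~8 observations, so the
  pointwise profile has 25–35 % sampling noise; its median over a segment
  is accurate to ~10 %. Tests therefore check the profile's median, not
  every interval.

Change points are located at the largest jump of $\log \sigma^2_m$ between
adjacent intervals. The log scale matters: absolute jumps are dominated by
sampling noise in the high-variance regime (3/20 correct localizations
versus 20/20 on the log scale in the two-regime experiment: 0.2 → 5 m²/s
at fix 150 of 300, tolerance ± 3 fixes).

Setting `allow_breakpoints=False` reduces the same code path to the
classical constant-variance Brownian bridge (verified bitwise).

## UD rasterization

The UD is the time integral of the bridge density. Each fix interval is
discretized at `substeps = 10` midpoint times, each weighted
$\Delta t/\mathrm{substeps}$; the per-cell mass of each evaluation is
computed exactly as the product of 1-D Gaussian CDF differences at cell
edges. Cell-center evaluation (density × area) was tried first and erred
by up to 19 % of the peak cell when the bridge SD is comparable to the
1 km cell, and radius-truncated accumulation windows broke exact mirror
symmetry; exact edge integration removes both problems, leaving the
temporal discretization as the only approximation (measured ≤ 2 % of the
peak cell against a 1000-substep, 5×5 subsampled oracle). The surface is
normalized to sum to 1, and a hard error is raised if the grid fails to
contain the 3-SD envelope of any bridge.

Grid extent: the segment's bounding box buffered by
max(30 km, 3 × max bridge SD), snapped to cell edges — enough to capture
≥ 99.7 % of bridge mass. Cells are half-open
$[x_0+is, x_0+(i+1)s) \times [y_0+js, y_0+(j+1)s)$ so any point, including
one on a shared edge, belongs to exactly one cell.

## Segmentation

"Continuous directional movement" is operationalized at the day level:
daily net north–south displacement (last fix of one UTC day minus last fix
of the previous observed day) is signed against a 20 km/day threshold;
maximal same-sign runs tolerate at most 1 interior below-threshold
(stopover) day; a run qualifies as a migration segment when its total net
displacement is ≥ 100 km. Day-level runs are robust to hourly jitter;
both knobs (`min_daily_km`, `max_stopover_days`) are exposed in the
config. Direction is the sign of net $\Delta y$ (projected northing),
appropriate for latitudinal corridors. Segments are padded with ~24 h of
fixes on each side so the model covers the full movement, and the padded
fix count is what the ≥ 17-fix exclusion tests (the padding fixes shape
the modeled track). Repeated migrations within a season yield separate
segments.

## Population surface and categories

The population UD is the fix-count-weighted mean of segment UDs
(re-normalized). Weighting by fixes rather than equally per track ties
exposure to the time an animal spent on the landscape; the weight is the
padded segment's fix count, since those fixes shaped the surface.

Ordination into categories offers two modes because "top 20 %" admits two
readings:

- **count-quantile** (default): rank nonzero cells by value, descending,
  ties broken by row-major cell index; the top 20 % *of cells* are
  category 20, the next 20 % category 40, … Categories are equal-sized to
  within one cell.
- **volume-quantile**: walk the same ranking accumulating mass; cells up
  to 20 % *of total UD mass* are category 20, etc. This concentrates
  category 20 onto few high cells, the pattern usually drawn as corridor
  "cores".

Cells below $10^{-12} \times$ the max cell are background (floating-point
dust from the normalization). All tie-breaks are deterministic.

## Hazard overlay

Turbines with total height ≥ 100 m above ground are assigned to the
category of their containing cell; turbines lacking a height attribute are
excluded from the filtered set (and logged), and out-of-extent turbines
are reported, never silently dropped, so counts always conserve.
Wind-power-class rasters (integer classes 1–7 at 50 m AGL) are resampled
to the category grid by nearest neighbor — bilinear would invent classes —
and cells with class ≥ 3 (the commercially viable classes) are tallied per
category at 100 ha per 1 km cell. Report percentages are integers rounded
half away from zero, and the turbine denominator is the full filtered
total (all categories + background + out-of-extent) unless the caller
supplies one.

## Synthetic data

The generators emulate the study conditions the pipeline targets:

- **Tracks**: hourly fixes 06:00–19:00 local plus one midnight fix (15
  per day, matching a solar transmitter duty cycle; the window of 17 is
  the ceiling of fixes per day), isotropic Gaussian GPS error of 18 m,
  and a behavioral schedule of resident / migrating-north /
  migrating-south phases. The true path is Brownian motion with
  piecewise-constant $\sigma^2_m$ (an independent regime schedule, so
  change-point recovery has ground truth) plus drift along a corridor
  polyline at a configurable speed (default in the demo: 60 km/day over a
  360 km corridor). The generator records true positions, per-interval
  variance, change-point times, and phase labels.
- **Turbines**: a Poisson-cluster process — uniform cluster centers,
  Gaussian scatter (SD 2 km) resampled into the extent — with uniform
  heights in 80–160 m. The demo confines clusters to a 2 km buffer around
  the corridor actually used, emulating ridgeline wind farms.
- **Wind power class**: a Gaussian-filtered white-noise field thresholded
  at its own empirical quantiles, so marginal class frequencies match a
  target distribution exactly up to rounding while remaining spatially
  smooth. The default class mix puts 40 % of cells at class ≥ 3.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: thermal and orographic lift (drift is constant
along the corridor, not terrain-driven), altitude, behavioral state
switching within a day, missed fixes and irregular duty cycles, spatially
correlated GPS error, geodesy and projection distortion, and any coupling
between wind power class and turbine placement beyond the corridor buffer.

## Problem sizes

Monte-Carlo experiments use 20 seeds throughout: variance recovery on
200-fix pure-Brownian tracks (median within 15 % of truth), change-point
localization on 300-fix two-regime tracks (± 3 fixes in ≥ 80 % of seeds).
The demo pipeline runs 3 individuals for 28 days (1,080 fixes, 6
segments) on a ~65 × 425 km grid of 1 km cells; the full suite runs in
about half a minute and the acceptance script in under one.

## Known limitations

- The one-breakpoint-per-window model space approximates multi-regime
  structure only through window averaging; very short regimes
  (≪ window) are smoothed over.
- The variance profile is biased near regime boundaries (windows
  straddling a change mix regimes), which is why change-point location
  uses the log-scale jump rather than profile values directly.
- Count-quantile categories equalize cell counts, not use intensity; the
  volume mode is the one that isolates high-use cores. Area tables from
  the two modes are not comparable.
- No inferential statistics: the pipeline maps exposure, it does not
  estimate collision rates or test hypotheses about avoidance.
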