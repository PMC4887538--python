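# Methods

This note documents the models, conventions and design choices behind
`canopyscale`, and what the synthetic experiments do and do not show.

## Synthetic forest model

Stems are a homogeneous Poisson process within each management unit at
the unit's target density λ (stems m⁻²). DBH is Weibull(shape, scale)
per unit — the standard diameter-distribution model for even-aged stands
— floored at 1 cm. Height follows a saturating allometry
h = h_max·(1 − e^(−k·d))^c with defaults h_max = 35 m, k = 0.0528,
c = 1.2, placing a 40 cm DBH beech at ≈ 30 m. Crown radius
(0.5 + 0.05·d m) and crown base (1 + 0.25·d m, capped at 0.9·h) are
linear in DBH. A stem whose allometric height is ≤ 1.3 m is redrawn
(bounded retries). Terrain is an analytic surface (tilted plane plus a
sinusoidal swell), so DTM accuracy can be scored exactly.

Stem wood volume is v = (π/4)·(d/100)²·h·f with form factor f = 0.5 by
default; f folds stem taper into one configurable coefficient. `true_volume`
uses stem-localised accounting: a tree counts entirely for the polygon
containing its stem coordinate, regardless of where its crown reaches —
exactly the convention of field inventories, and the root of the edge
effect once LiDAR clips canopy by the plot boundary instead.

The experiment scenes (`experiments.make_scene`) couple unit density to
unit stem size with a Reineke-type self-thinning rule
(λ ∝ scale^−1.6, ≈ 300–450 stems ha⁻¹ at 25 cm DBH, drawn per unit with
scale ∈ [16, 40] cm). Independent draws of density and size produce
stands that are simultaneously dense and large — structurally
unrealistic and dominated by a pure density signal; the coupled mosaic
behaves like a managed even-aged landscape where canopy height carries
most of the volume gradient.

## LiDAR simulator

Pulses form a Poisson pattern at the configured density (default
16 m⁻², leaf-on) and descend vertically (no scan-angle geometry —
scan-angle effects are out of scope). Crowns are vertical ellipsoids
between crown base and tree top. For each crown a pulse pierces, a
vegetation return is generated at the upper intersection with
probability (1 − e^(−κL))·e^(−κA), where L is the vertical chord through
that crown, A the canopy path already traversed, and κ the per-metre
interception probability (default 0.3 m⁻¹). A ground return is generated
with the residual transmission e^(−κ·total) when fewer than
`max_returns_per_pulse` (default 4) returns were emitted. All returns
get Gaussian vertical noise (default sd 0.1 m). Return numbers are 1..k
from the top. Everything is deterministic given the seed.

Not emulated: full waveform, leaf-off phenology, species-specific taper,
topographic pulse occlusion, intensity. Passing tests therefore
demonstrate the *mechanisms* (edge effects, misregistration, sampling
noise, aggregation), not radiometric realism.

## Field-inventory simulation and the GPS-error mechanism

Two designs: `census_1ha` records every stem with DBH > 7 cm (strict) in
a 100 m square; `nested_0.05ha` records stems out to 12.5 m with the
three-ring rule below. Stem selection always uses the **true** plot
centre — the crew stands at the physical point — while the **recorded**
centre carries a bivariate Gaussian GPS offset (default sd 2 m; no
published magnitude exists for the emulated network, so this is a chosen
default) and is what the LiDAR clip uses. This asymmetry *is* the
misregistration mechanism: the field data are right, the clip is shifted.
Measured DBH gets Gaussian error (default sd 0.3 cm), truncated positive.

Nested rings and per-hectare expansion factors (EF = 10⁴/(π r²)):

| ring radius | DBH class | EF |
| --- | --- | --- |
| 5 m | d ≤ 7 cm | 127.32 |
| 7 m | 7 < d < 12 cm | 64.98 |
| 12.5 m | d ≥ 12 cm | 20.37 |

The printed field protocol leaves DBH exactly 12 cm unassigned
("< 12 cm" then "> 12 cm"); the classes are closed here at the outer
ring (d ≥ 12) so they partition (0, ∞). Expansion uses the true ring
areas — the nominal "0.05 ha" plot is geometrically
π·12.5² = 490.9 m² = 0.0491 ha.

## Point-cloud processing

Ground classification is a progressive-TIN densification: lowest return
per 2 m cell as seeds; seeds standing higher above their 5×5-cell
neighbourhood minimum than a 50 % slope plus 3·z_tol allows are rejected
(they are canopy over fully occluded cells); then 3 iterations accept
every return within z_tol = 0.3 m of a TIN through the per-cell medians
of the current ground set. Median TIN nodes matter twice: they suppress
the sensor noise of individual returns, and they remove the low bias a
lowest-point surface inherits from the noise minimum. On simulated
scenes the classifier recovers ≥ 99 % of true ground returns with no
canopy contamination. The algorithm is z-shift invariant.

The DTM is a Delaunay TIN over ground points, linearly interpolated at
1 m cell centres; cells outside the convex hull are nodata.
Normalisation subtracts the bilinear DTM elevation (smoother than
nearest-cell); points over nodata are dropped. Plot clipping uses a
closed boundary — a return exactly on the plot edge belongs to the plot.
All coordinates are planar metres in a projected CRS; no reprojection is
implemented.

## Canopy metrics

Vegetation returns are those with normalised height ≥ 0.5 m.
Conventions, fixed so tests can be exact: variance with n−1; skewness
and kurtosis as biased standardised 3rd/4th moments (kurtosis not
excess); percentiles by linear interpolation at rank p(n−1)+1 ("type 7");
L-moments by the unbiased probability-weighted-moment estimators; the
mode as the midpoint of the fullest 0.5 m histogram bin (ties to the
lowest bin) — continuous heights have no natural mode, so a binned
definition is required, and it makes modCH/MADmod the only metrics that
are not exactly scale-equivariant. Cover uses first returns
(vegetation-first / all-first), density all returns; both are percents.
Strata s2..s40 count vegetation returns in 2 m bins below 40 m; returns
above 40 m stay in every other metric. Degenerate plots produce NaN
markers, never exceptions, so wall-to-wall gridding proceeds; a bare
cell (returns but no vegetation returns) predicts volume 0.

## Volume modelling

Training uses a random 70/30 split (|train| = round(0.7 n)). Stepwise
selection is bidirectional from the intercept-only model, one add-or-drop
move per step, minimising AIC = n·ln(RSS/n) + 2(p+1); RSS is floored at
numerical-noise scale so perfect fits terminate. The implementation
reproduces R's `step()` selections and coefficients exactly on shared
fixtures. On pure-noise candidates AIC admits a handful of spurious
terms (measured: mean ≈ 4.7 of 30 candidates) — the classical liberal
behaviour of AIC, reproduced faithfully rather than suppressed.
Negative predictions are floored at 0 for mapping (volume cannot be
negative); the raw value is available. The experiment fits use a
candidate pool of the classical area-based predictors (MCH, CV, var,
q20, q40, q70, q90, kurt, cover, density); raw counts and strata are
excluded by default as acquisition-dependent.

## Landscape scaling

The 1 ha model predicts on 100 m square cells, the 0.05 ha model on
√500 ≈ 22.36 m cells (circles cannot tile; the equal-area square is
used). Unit aggregation intersects cells with unit polygons and
area-weights partial cells, so unit totals plus the outside-units
remainder equal the whole-map total over the map footprint. Model
comparison reports R² of the OLS fit between unit totals and RMSE about
the identity line (difference-between-models semantics); the
regression-line RMSE is attached for reference.

## Sample-size permutation analysis

For each sample size x: draw x plots without replacement, fit simple OLS
volume ~ MCH, record R² and RMSE; 1000 repetitions per size
(independent redraws across repetitions), all closed-form and
vectorised. Subsets with constant predictor are redrawn and counted.
`summarize_stability` reports five-number summaries per size and a
stability threshold: the smallest x from which IQR(R²) stays ≤ a
tolerance (default 0.05 R² units — an explicit formalisation of a
judgement usually made by eye on box plots). One known property of this
analysis: sample R² is inflated by ≈ (1−ρ²)/n at small n, so the
per-size *median* R² declines by ~0.01 over x = 25…1000 even when the
underlying relationship is constant; the median is visually flat but not
statistically flat under a high-powered trend test.

## Experiment problem sizes

Replicate experiments use 360 m scenes (3×3 unit mosaic), 25 one-hectare
plots and 100 nested plots per scene, survey defaults for the LiDAR
(16 pulses m⁻²), and 20 replicate scenes for the plot-size comparison;
the inventory-closure check uses a 300 m homogeneous stand with 500
nested plots and a 3×3 tiling of census plots; the permutation analysis
uses 1100 (0.05 ha) and 50 (1 ha) synthetic plots. Inside the replicate
experiments the simulator's own ground/vegetation labels and a
median-node TIN DTM stand in for re-running the progressive classifier
on every scene; the classifier itself is validated separately against
the simulator labels.

## Known limitations

* Crown ellipsoids and vertical-only pulses make percentile profiles
  smoother than real beech canopies; absolute metric values should not
  be compared against real surveys, only mechanisms and orderings.
* The stem-volume form factor is a single scalar; no taper equations,
  bark deduction or species-specific wood densities.
* GPS error is isotropic Gaussian; real receivers err worse under canopy.
* Unit polygons are rectangles in the bundled scene generator; the
  aggregation code accepts arbitrary polygons.
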