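# Methods

This note documents the models, numerical choices and simulation designs
behind `understory_hsm`, in the order the pipeline runs them.

## The understory-density metric

Understory density of a grid cell is `100 × #{returns with low ≤ h < high}
/ #{all returns}`, with the stratum `[0.5, 5.0)` m half-open at the top
(the boundary side is a convention; the source material leaves it
unstated).  The grid is 12.5 m (the Swedish forestry-map standard) with a
lower-left origin, half-open cells, and cells addressed by their centers —
an explicit convention so zonal statistics are unambiguous.  Heights are
normalized by subtracting a bilinearly interpolated DEM.  Three rules keep
the metric honest:

- cells with zero returns are no-data, never 0% — an empty cell is absence
  of evidence, not evidence of an open understory;
- forest pixels clear-cut before LiDAR acquisition, or thinned at any
  recorded date, are no-data (the vegetation the sensor saw does not match
  what the birds experienced);
- a nest × radius summary is valid only if no-data cells are ≤ 5% of the
  forest cells inside the buffer.  The denominator of that fraction is
  forest member cells (the source is silent on whether non-forest cells
  count; forest cells are what the metric is about).

Buffer membership is by cell center.  The radius schedule is the 15 m nest
radius (GPS uncertainty) plus 100 radii out to the 460 m territory border.
The source text describes the larger radii as percent-of-territory-area
steps but also gives a 460 m border, and a 460 m disc is ≈ 66 ha, not the
stated 460 ha — the two statements cannot both hold.  The default schedule
honours both printed endpoints with equal-area increments
(`r_k = 460·√(k/100)`); a linear 15→460 m schedule is a config switch, and
any explicit radius list is accepted.

## The breeding-success mixed model

Bernoulli GLMM with a logit link; fixed effects: intercept, study area
(managed/unmanaged; only two levels, so a fixed effect), proximity class
(close = distance to nearest settlement strictly below the breakpoint),
the understory term, and the proximity × understory interaction; crossed
random intercepts for year and both breeders' identities.  Understory
enters as the natural log of the percentage, floored at 0.1% (configurable
`ud_log_floor`) so empty-understory pixels stay finite.  Covariates are
not standardized by default (a config flag enables centering, applied
identically across compared models).  When the forest-cover covariate of
the scale analysis is (near-)constant — fully forested buffers — it is
dropped from the design rather than fitting a singular model.

### Fitting

The fitter maximizes the Laplace approximation of the marginal likelihood,
the `glmer` objective.  For fixed random-effect SDs the fixed effects and
random-effect modes are found by penalized IRLS; the outer optimization
over (β, log σ) runs in two stages — a profiled stage that treats β as the
joint PIRLS mode (cheap, good starting values) and a joint BFGS stage on
the exact Laplace objective, whose inverse-Hessian estimate can be carried
between the many nearly identical refits of a model scan.  Wald SEs come
from the fixed-effect block of the inverse joint penalized Hessian at the
optimum, conditional on the estimated variance components (the standard
mixed-model convention).  Default start: β from a plain logistic fit,
σ² = 0.1 per component; the fit is deterministic.

The linear algebra exploits the crossed-intercept structure instead of a
generic sparse solver: each factor's own block of the penalized Hessian is
diagonal; the smallest factor (year) is removed by a Schur complement; the
remaining breeder factors couple only through shared observations and
split into many small connected components (breeding-pair lineages) that
are factorized in size-batched dense operations.  A factorization is
O(n + q), which is what makes 50-replicate scan studies affordable.  The
test suite pins this machinery to two independent oracles: a 50-node
adaptive Gauss–Hermite quadrature on a single-factor toy (|Δ log L| <
0.05) and `lme4::glmer` on a crossed design (coefficients within 0.03,
log-likelihood within 0.02).

Variance components at the boundary are reported as exactly 0 below an SD
of 10⁻³.  Non-convergence falls back to scipy's L-BFGS-B on the same
objective and is flagged on the fit object.

### Model selection

AICc = −2 logL + 2k + 2k(k+1)/(n−k−1), with k counting fixed effects plus
variance components; since compared models share the random structure the
choice is inert for rankings but stated for reproducibility.  The
breakpoint scan refits the full model for every candidate on the
500–3,500 m / 50 m grid clipped to the 10th–90th percentile of nest
distances (rounded to the grid step); candidates leaving fewer than 10
nests in either class are skipped; AICc ties break toward the smaller
distance.  The transform comparison (log / linear / quadratic understory;
the interaction accompanies every understory term of the active transform)
keeps n and the random structure identical across the three fits.  The
sensitivity table refits across a breakpoint range and flags candidates
where the interaction's estimate ± SE interval crosses zero.

R²: marginal = var(Xβ̂) / (var(Xβ̂) + Σσ̂² + π²/3), conditional replaces the
numerator with var(Xβ̂) + Σσ̂².  VIF_j = 1/(1−R²_j) from OLS of column j on
the remaining non-intercept columns plus an intercept.

## The predator proxy

Eurasian jays overwinter at feeders, so their occurrence near nests is
modelled as logistic in the distance to the nearest settlement (plain ML
via statsmodels; observations treated as independent bouts).  Switch
distance d* = −α₀/α₁ with delta-method SE from the coefficient covariance
(gradient (−1/α₁, α₀/α₁²)); complete separation is detected beforehand and
reported as the separating midpoint with infinite SE.  No single
"variance explained" is canonical for a binary fit, so three are always
reported side by side: squared Pearson correlation between fitted
probability and outcome, McFadden's 1 − logL/logL₀, and Tjur's
discrimination coefficient.

## Scale of effect

One model per radius, with the understory term replaced by the mean
density inside that radius and the forest-cover proportion at the same
radius as a covariate (included at every radius, the nest radius too, for
comparability).  Only nests valid at all radii enter, so n is constant.
The per-radius marginal R² is read against the correlation of that
radius' density with the nest-scale density: a radius that merely
correlates with the nest scale is not independent evidence.

`effective_band` replaces the visual judgement "the pattern holds to about
80 m" with an explicit rule: the contiguous band from the nest radius
while marginal R² ≥ retention × (max R² over admissible radii), default
retention 0.9, where admissible means correlation with the nest scale
≥ 0.5.  Decorrelated radii can neither join the band nor set the
reference maximum — at large radii the density variance shrinks and the
per-radius fit can return erratically large R² values that would
otherwise poison the threshold.

## Landscape prediction and validation

Per-pixel prediction uses fixed effects only (random effects at zero —
population-level prediction) with the study-area term at a configurable
reference (default: the pixel's own side of the managed/unmanaged split
when known, else "managed").  Non-forest pixels and pixels whose
neighborhood-mean density falls outside the per-proximity-class nesting
range observed at actual nests are set to exactly 0; pixels without a
density value stay no-data (unknown is not unsuitable).  Aggregation to
the coarse grid is the mean over fine cells whose centers fall in the
coarse cell, no-data propagating only if every member is no-data.  Both
coarse maps are min–max normalized and differenced as occurrence −
prediction, so negative values mean over-predicted breeding success; the
Pearson correlation uses the non-normalized values.  A constant raster has
no min–max scale; the comparison then reports the correlation as undefined
and maps the constant layer to zero rather than failing.

## The synthetic scenes

`generate_landscape` draws the understory field as Gaussian white noise
smoothed to a correlation range (default 100 m), restandardized to mean
13% / SD 6% — chosen to match the study site's published per-class
summaries (13.1 ± 4.9 far, 12.6 ± 7.2 close) — and clipped to [0, 100].
Settlements are a homogeneous Poisson process (default 0.05/km², the
order of magnitude of the sparsely settled study region; simulations that
need a richer distance gradient pass a higher intensity explicitly).  The
western 53/83 of the extent is "managed", mirroring the 53 km² + 30 km²
study areas.  `generate_point_cloud` draws per-cell return counts as
Poisson(pulse density × cell area) and thins them binomially by the field;
within-stratum heights are uniform on purpose — only stratum membership
feeds the metric.  `generate_nests` gives each pair a fixed territory and
a yearly nest on a forest cell within 150 m of its center; each breeder
persists between seasons with probability 0.8 (geometric tenure inducing
the crossed repeated-measures structure; divorce and re-pairing across
territories are ignored — only the crossed-factor structure matters to
the fitter).  Passing an infinite jitter turns site fidelity off, which
the scale experiments use to isolate spatial-scale questions from
territory clustering.  Outcomes follow the logistic truth with the
published coefficient set as default and σ² = 0.5 per random factor — the
source reports no variance components, so this moderate default is
explicit and configurable.  Every generator draws from its own
seed-derived stream, so stages can be regenerated independently.

What the scenes do not emulate: real LiDAR acquisition geometry (scan
angle, multiple returns per pulse), vegetation growth between acquisition
and breeding years, non-Poisson settlement patterns, and behavioural
responses of predators beyond the distance effect.  Green recovery tests
therefore demonstrate that the estimators recover the generating process
they assume, not that the ecological model is right.

## Simulation designs used by the recovery tests

Problem sizes are the package's own choices and are fixed in the tests:

- **Coefficient recovery / coverage**: one dataset of n = 5,000 (16
  seasons) for the 2-SE check; 200 replicates of n = 500 (10 seasons) for
  Wald-interval coverage (observed ≥ 92% per coefficient).
- **Breakpoint recovery**: 50 datasets of n = 2,000, truth 1,450 m with
  the full published effect set; recovery within ± 50 m.
- **Scale recovery**: 20 replicates, n = 1,000 spatially independent
  nests, field correlation range 70 m, a *linear* density effect confined
  to the 15 m nest scale (η = −4 + 0.2·ud), thinned 10-radius schedule.
  The linear construction is deliberate: with a log effect on a field
  whose density approaches zero in patches, the log transform amplifies
  low-density measurement extremes at small radii and the per-radius R²
  profile becomes noisy enough to obscure the scale signal — an
  instructive property of the log model, but not what this experiment
  measures.  Under the linear construction the R² profile tracks the
  buffer-mean decorrelation and the band's upper edge falls in 60–120 m.
- **End-to-end**: a 5 × 5 km scene at 0.5 returns/m² (≈ 12.5 M returns),
  600 nests, validation on a 500 m coarse grid — a 2 km validation grid,
  as used for a region of many thousand km², would leave only ~4 cells on
  a 5 km scene.  Bias-free occurrence gives map correlations ≈ 0.99; an
  injected −0.15 occurrence deficit in the southern half shifts that
  region's difference-map quantiles and leaves the north centered.

## Known limitations

- The Laplace approximation shares `glmer`'s small-cluster bias for binary
  data; no adaptive-quadrature refinement is offered for crossed designs
  (none exists in closed form; the quadrature oracle covers the
  single-factor case).
- Complete separation in the breeding model is not specially handled
  beyond the optimizer's bounds; the predator module detects it
  explicitly.
- The LAS/LAZ and GeoTIFF binary formats are not read; point clouds are
  whitespace XYZ text and rasters ESRI ASCII grids.
- The pipeline assumes a projected metric CRS throughout and never
  reprojects; multi-date LiDAR mosaics are accepted as a single pre-merged
  input.
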