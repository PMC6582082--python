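# Methods

## Model

`breedsuit` fits the maximum-entropy presence-background model: a
distribution P(x) ∝ exp(λ·f(x)) over the cells of the covariate stack
(the "background"), chosen so that the expected features under P match
the features observed at presence cells, subject to an L1 penalty. The
fitted λ minimizes

J(λ) = −(1/m)·Σ_presences λ·f(xᵢ) + log Σ_background exp(λ·f(x)) + Σₖ βₖ|λₖ|

This is convex; the penalty both regularizes and performs variable
selection, which is the standard answer to correlated covariate stacks
in this model family (no pre-selection of variables is attempted).

### Features

Covariates are min–max scaled to [0,1] using background extremes, and
values outside that range are clamped at prediction time so
extrapolation saturates instead of exploding. Feature classes:

- linear — the scaled covariate;
- quadratic — its square;
- product — pairwise products of scaled covariates;
- hinge — max(0, (v−k)/(max−k)) at `n_hinge_knots` evenly spaced knots
  per covariate (default 10), plus reverse hinges at the interior
  knots.

All features lie in [0,1] on the background; constant covariates are
dropped and recorded. Which classes are enabled defaults on the
presence count m, following common MaxEnt practice: m<10 linear only;
10–14 +quadratic; 15–79 +hinge; ≥80 +product. The per-class penalty
constants β_class(m) are the reference MaxEnt/maxnet tables
(linear 1→0.05, quadratic 1.3→0.05, product 2.6→0.05 over m = 0→100,
hinge fixed at 0.5), linearly interpolated; the full penalty is
βₖ = reg_multiplier · β_class(m) · sdₖ(presence features)/√m, with sdₖ
floored at 10⁻⁶ so no coordinate is ever exactly penalty-free.

### Optimizer

Cyclic coordinate descent. Each coordinate takes a proximal-Newton
step — soft-threshold(λₖ − gₖ/hₖ, βₖ/hₖ) with gₖ and hₖ the fitted
distribution's feature mean-gap and variance — guarded by a halving
line search that enforces monotone objective decrease (the background
score vector is cached and updated incrementally, so a sweep costs
O(features × background)). Convergence means the objective fell by
less than `tol` (default 10⁻⁷) over a sweep; hitting `max_iter`
(default 500) reports `converged=False` rather than raising. On small
instances the solution agrees with an independent convex solver to
10⁻⁶ in objective (tested). The per-coordinate objective decreases are
recorded and aggregated to source variables as the "path" variable
contribution (product features split evenly between their parents).

### Output scales

- raw: exp(λ·f(x) − log Z), a probability distribution over the
  background cells (sums to 1 when the background is all cells);
- logistic: c·raw/(1 + c·raw) with c = e^H, H the entropy of the
  fitted distribution — the conventional [0,1] rescaling that assigns
  0.5 to a typical presence-like cell (default prevalence 0.5).

The background is every non-missing cell up to 10,000, beyond which a
seeded uniform sample of 10,000 cells is used. Presences are
deduplicated to one per raster cell before fitting.

## Evaluation

Minimum training presence: the threshold is the smallest predicted
value among training presences, and the comparison is ≥, so training
omission is exactly zero by construction. AUC is the Mann–Whitney rank
statistic of presences against background cells (ties get half
credit) — with no held-out data it is a training AUC and is labelled
as such. The omission test is the exact binomial tail P(X ≥ k) with
X ~ Bin(n, a), a the binary map's fractional predicted area; no normal
approximation is used because small n is the common case.

## Spatial cross-validation

A degree grid (default 1°×1°, anchored at integer multiples of the
cell size, half-open boxes) is laid over the study mask, and cells
with mean livestock density strictly greater than 10 individuals/km²
are retained. For each retained cell containing occurrences, all its
records are removed, the model is refit, and the refit model's mean
suitability over the cell's raster cells is recorded. Retained cells
without occurrences receive `n_random` (default 30) uniform draws over
their non-missing raster cells, scored at cell centers.

Because training is presence-only, "removing" random absence points
from the training set cannot change the fit; absence cells are
therefore scored with the full-data model (a `refit_for_absences`
switch reproduces the literal per-cell refit, which is equivalent).
The two groups of cell means are compared with Welch's
unequal-variance t-test (group sizes and spreads differ) and returned
together with kernel-density series for plotting.

## Region ranking and comparison

Cell areas use the spherical formula R²·Δλ·(sin φ₂ − sin φ₁),
R = 6371.0088 km, so areas depend only on the grid row and per-region
sums reproduce map-wide totals exactly; no projected CRS is needed.
Regions are ranked by percent suitable area, descending, ties broken
alphabetically; the default reports the top 4. The two-breed
comparison map is log₂(a+ε) − log₂(b+ε) (ε = 10⁻⁶ guards zero
suitability and the subtraction form makes swap-antisymmetry exact to
the bit); |value| ≤ 0.5 (half a doubling) is labelled neutral.

## Synthetic worlds

The generator emulates the pipeline's four inputs with known truth:

- Covariates: white noise convolved with a Gaussian kernel
  (`correlation_length` = kernel sd in cells, wraparound boundaries),
  standardized to mean 0/variance 1. Inter-layer correlation comes
  from mixing a shared latent field, layerᵢ = α·common +
  √(1−α²)·indepᵢ with α = √cross_correlation, so every pair correlates
  at ≈ cross_correlation.
- Presences: cells drawn without replacement with probability ∝
  exp(intercept + Σ coeff·covariate) via the Gumbel top-k trick, at
  most one per cell (matching the fitting-side deduplication); points
  are cell centers on a plate-carrée degree grid.
- Regions: a Voronoi partition around random seed cells.
- Density: baseline ± ≤10 % smooth noise, with an exact
  `low_fraction` of cells forced to baseline/100.

Default world: 100×100 cells of 0.1° (a 10°×10° area, so the default
1° CV grid has 100 cells), five covariates with correlation length 5
cells and cross-correlation 0.3 (environmental layers are mutually
correlated in practice, but far from collinear), truth +3·var1 −
3·var2 with three inert covariates, 200 presences, nine regions (the
motivating use case is a country with nine regional states), density
baseline 50 birds/km² with a quarter of cells far below the
10 birds/km² screen.

What a green test does and does not establish: the simulator draws
presences *exactly* from the model family being fit (log-linear in the
covariates, no sampling bias, no observation error, stationary
fields). Passing recovery and CV checks therefore validates the
implementation — optimizer, scales, thresholds, bookkeeping — not the
ecological adequacy of MaxEnt for any real breed; real occurrence data
add spatial reporting bias, covariate measurement error and
non-stationarity that the generator deliberately omits.

## Numerical and design choices

- Cells are half-open ([x, x+w) in lon, (y−w, y] in lat): a point on a
  boundary belongs to the cell to its south-east, making containment
  deterministic.
- Nodata is unioned across layers: the model needs complete covariate
  vectors, so a cell missing anywhere is missing everywhere.
- The density screen is strict (> 10), so a cell at exactly the
  threshold is dropped.
- Thresholding uses ≥, so the minimum training presence itself is
  suitable.
- Degenerate inputs: all presences in one raster cell fits with a
  warning; a single occupied CV grid cell yields an empty fold list
  with a warning; identical comparison groups return t = 0, p = 1.
- Raster I/O uses the ESRI ASCII grid text format with square cells;
  the package requires pre-aligned inputs and does not reproject.

## Limitations

- No sample-bias correction, threshold/category features, or
  projection to future climates.
- AUC and the omission test are computed on training data by default;
  the spatial CV is the only out-of-sample check.
- The spherical area model assumes a geographic (degree) grid; data on
  a projected grid would need areas supplied externally.
- Region labels must be rasterized onto the stack grid; polygon
  geometry is out of scope.
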