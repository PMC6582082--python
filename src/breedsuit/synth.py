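"""Virtual landscapes with known truth for end-to-end pipeline testing.

The generator emulates the four inputs the suitability pipeline needs:
spatially autocorrelated and inter-correlated covariate layers
(Gaussian random fields via kernel-smoothed white noise), presence
points drawn from a known log-linear suitability surface, a Voronoi
partition standing in for administrative regions, and a livestock
density layer with a controlled fraction of low-density cells.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geodata import (
    DensityRaster,
    GridTransform,
    OccurrenceSet,
    RasterStack,
    RegionMap,
)


@dataclass
class TrueSuitability:
    """Known log-linear suitability truth on standardized covariates.

    Relative occurrence intensity is exp(intercept + Σ coeff·covariate);
    only the linear predictor matters for sampling, so the intercept is
    a convenience for absolute-scale bookkeeping.
    """

    coefficients: dict[str, float]
    intercept: float = 0.0

    def linear_predictor(self, stack: RasterStack) -> np.ndarray:
        """Grid of intercept + Σ coeff·covariate (NaN on missing cells)."""
        missing_names = [n for n in self.coefficients if n not in stack.layers]
        if missing_names:
            raise KeyError(
                f"truth covariates {missing_names} not in stack layers "
                f"{stack.layer_names}"
            )
        eta = np.full(stack.shape, float(self.intercept))
        for name, coeff in self.coefficients.items():
            eta += coeff * stack.layers[name]
        eta[stack.missing] = np.nan
        return eta


@dataclass
class SyntheticWorld:
    """A complete simulated study system: landscape, truth, observations."""

    stack: RasterStack
    truth: TrueSuitability
    occurrences: OccurrenceSet
    regions: RegionMap
    density: DensityRaster
    seed: int
    params: dict = field(default_factory=dict)


def _smooth_standard_field(shape, sigma, rng) -> np.ndarray:
    """Kernel-smoothed white noise, standardized to mean 0 / variance 1."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = gaussian_filter(z, sigma=sigma, mode="wrap")
    z = z - z.mean()
    sd = z.std()
    if sd == 0:  # pathological (e.g. huge sigma on tiny grid)
        return np.zeros(shape)
    return z / sd


def generate_covariate_stack(n_rows: int, n_cols: int, n_vars: int,
                             correlation_length: float,
                             cross_correlation: float, seed: int,
                             west: float = 0.0, north: float | None = None,
                             cellsize: float = 0.1,
                             name_prefix: str = "var") -> RasterStack:
    """Simulate ``n_vars`` standardized, spatially autocorrelated covariates.

    Each layer is white noise convolved with a Gaussian kernel of
    standard deviation ``correlation_length`` (in cells), standardized
    to zero mean and unit variance over cells.  Pairwise inter-layer
    correlation ≈ ``cross_correlation`` is induced by mixing a shared
    latent field: layer_i = α·common + √(1−α²)·independent_i with
    α = √cross_correlation, so corr(layer_i, layer_j) = α².
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError(f"grid must be at least 8×8, got {n_rows}×{n_cols}")
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")
    if not 0 <= cross_correlation <= 1:
        raise ValueError("cross_correlation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alpha = np.sqrt(cross_correlation)
    common = _smooth_standard_field((n_rows, n_cols), correlation_length, rng)
    layers: dict[str, np.ndarray] = {}
    for i in range(n_vars):
        indep = _smooth_standard_field((n_rows, n_cols), correlation_length, rng)
        mixed = alpha * common + np.sqrt(1.0 - alpha**2) * indep
        mixed = mixed - mixed.mean()
        mixed = mixed / mixed.std()
        layers[f"{name_prefix}{i + 1}"] = mixed
    if north is None:
        north = n_rows * cellsize
    transform = GridTransform(west=west, north=north, cellsize=cellsize)
    return RasterStack(layers=layers, transform=transform,
                       missing=np.zeros((n_rows, n_cols), dtype=bool))


def sample_presences(stack: RasterStack, truth: TrueSuitability,
                     n_points: int, seed: int,
                     breed: str = "synthetic") -> OccurrenceSet:
    """Draw presence cells ∝ exp(linear predictor), one per cell at most.

    Without-replacement sampling uses the Gumbel top-k trick (add i.i.d.
    Gumbel noise to the log-intensities and take the k largest), which
    realizes the sequential exponential-tilting draw deterministically
    for a fixed seed.  Returned points are sampled cell centers.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_points > stack.n_valid:
        raise ValueError(
            f"n_points={n_points} exceeds the {stack.n_valid} usable cells"
        )
    eta_grid = truth.linear_predictor(stack)
    rows, cols = stack.valid_indices()
    eta = eta_grid[rows, cols]
    rng = np.random.default_rng(seed)
    gumbel = rng.gumbel(size=eta.shape)
    order = np.argsort(eta + gumbel)[::-1][:n_points]
    lon, lat = stack.transform.cell_center(rows[order], cols[order])
    return OccurrenceSet(breed, np.column_stack([lon, lat]),
                         source_tag=f"synthetic(seed={seed})")


def generate_regions(stack: RasterStack, n_regions: int, seed: int) -> RegionMap:
    """Voronoi partition of the grid around random seed cells.

    Every non-missing cell gets a label in 1..n_regions (nearest seed
    cell in index space, ties to the lowest label); missing cells get 0.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > stack.n_valid:
        raise ValueError("n_regions exceeds the number of usable cells")
    rng = np.random.default_rng(seed)
    rows, cols = stack.valid_indices()
    chosen = rng.choice(rows.size, size=n_regions, replace=False)
    seeds = np.column_stack([rows[chosen], cols[chosen]]).astype(float)
    cells = np.column_stack([rows, cols]).astype(float)
    d2 = ((cells[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # ties -> lowest seed index
    labels = np.zeros(stack.shape, dtype=int)
    labels[rows, cols] = nearest + 1
    names = {i + 1: f"region_{i + 1}" for i in range(n_regions)}
    return RegionMap(labels=labels, names=names)


def generate_density_raster(stack: RasterStack, baseline: float,
                            low_fraction: float, seed: int,
                            noise_sigma: float = 3.0) -> DensityRaster:
    """Density = baseline ± ≤10% smooth noise, with a low-density subset.

    Exactly ``round(low_fraction · n_valid)`` randomly placed cells are
    set to baseline/100, far below any plausible filter threshold; all
    other cells stay within [0.9, 1.1]·baseline.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if not 0 <= low_fraction <= 1:
        raise ValueError("low_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = _smooth_standard_field(stack.shape, noise_sigma, rng)
    scale = np.abs(g).max()
    rel = g / scale if scale > 0 else g
    values = baseline * (1.0 + 0.1 * rel)
    rows, cols = stack.valid_indices()
    n_low = int(round(low_fraction * rows.size))
    if n_low > 0:
        chosen = rng.choice(rows.size, size=n_low, replace=False)
        values[rows[chosen], cols[chosen]] = baseline / 100.0
    values[stack.missing] = np.nan
    return DensityRaster(values=values)


def true_suitability_surface(world_or_stack, truth: TrueSuitability | None = None
                             ) -> np.ndarray:
    """The truth's linear predictor grid (monotone in true intensity)."""
    if truth is None:
        world = world_or_stack
        return world.truth.linear_predictor(world.stack)
    return truth.linear_predictor(world_or_stack)


def generate_world(n_rows: int = 100, n_cols: int = 100, n_vars: int = 5,
                   correlation_length: float = 5.0,
                   cross_correlation: float = 0.3,
                   n_points: int = 200, n_regions: int = 9,
                   baseline_density: float = 50.0,
                   low_fraction: float = 0.25,
                   coefficients: dict[str, float] | None = None,
                   intercept: float = 0.0,
                   seed: int = 0,
                   breed: str = "synthetic",
                   cellsize: float = 0.1) -> SyntheticWorld:
    """Bundle a full synthetic study system with consistent sub-seeds.

    Defaults: a 100×100 grid of 0.1° cells (a 10°×10° study area), five
    covariates of which two drive the truth (coefficients +3 and −3 on
    var1/var2, the rest inert), 200 presences, nine regions, and a
    density layer averaging 50 birds/km² with a quarter of cells pushed
    far below the usual 10 birds/km² filter.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s) & 0x7FFFFFFF for s in ss.generate_state(4)]
    stack = generate_covariate_stack(
        n_rows, n_cols, n_vars, correlation_length, cross_correlation,
        seed=sub[0], cellsize=cellsize,
    )
    if coefficients is None:
        names = stack.layer_names
        coefficients = {names[0]: 3.0}
        if len(names) > 1:
            coefficients[names[1]] = -3.0
    truth = TrueSuitability(coefficients=dict(coefficients), intercept=intercept)
    occurrences = sample_presences(stack, truth, n_points, seed=sub[1], breed=breed)
    regions = generate_regions(stack, n_regions, seed=sub[2])
    density = generate_density_raster(stack, baseline_density, low_fraction,
                                      seed=sub[3])
    params = dict(n_rows=n_rows, n_cols=n_cols, n_vars=n_vars,
                  correlation_length=correlation_length,
                  cross_correlation=cross_correlation, n_points=n_points,
                  n_regions=n_regions, baseline_density=baseline_density,
                  low_fraction=low_fraction)
    return SyntheticWorld(stack=stack, truth=truth, occurrences=occurrences,
                          regions=regions, density=density, seed=seed,
                          params=params)
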