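"""Leave-grid-cell-out cross-validation against random pseudo-absence cells.

The study area is overlaid with a coarse degree grid (1°×1° by
default, anchored at integer multiples of the cell size) to limit the
optimism that spatial clustering induces in record-wise CV.  Cells are
first screened by mean livestock density (keeping cells where the
species plausibly occurs at all).  For every retained cell that
contains occurrences, all its records are held out, the model is refit
on the remainder, and the refit model's mean suitability over the cell
is recorded.  Retained cells with no occurrences receive random
"absence" points scored with the full-data model.  A Welch t-test
compares the two groups of cell means.

Note on the absence cells: because training is presence-only, removing
random absence points from the training set is a no-op, so absence
cells are scored with the full-data model by default; a per-cell refit
switch (``refit_for_absences``) reproduces the literal hold-out
procedure, which differs only by the (unchanged) training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde, ttest_ind

from .geodata import DensityRaster, OccurrenceSet, RasterStack, points_to_cells
from .maxent import MaxentConfig, MaxentModel, fit_occurrence_model

CellId = tuple[int, int]  # (floor(lon/size), floor(lat/size))


@dataclass
class DegreeGrid:
    """Coarse analysis grid over the study mask.

    Cells are half-open ``[lon_min, lon_min+s) × [lat_min, lat_min+s)``
    boxes at integer multiples of the cell size; only boxes containing
    at least one non-missing raster cell are retained.  ``members``
    maps each retained box to the (rows, cols) of its raster cells.
    """

    cell_size: float
    cells: list[CellId]
    members: dict[CellId, tuple[np.ndarray, np.ndarray]]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def lon_lat_min(self, cell: CellId) -> tuple[float, float]:
        return cell[0] * self.cell_size, cell[1] * self.cell_size

    def assign_points(self, lon, lat) -> list[CellId]:
        ix = np.floor(np.asarray(lon) / self.cell_size).astype(int)
        iy = np.floor(np.asarray(lat) / self.cell_size).astype(int)
        return list(zip(ix.tolist(), iy.tolist()))


def build_grid(stack: RasterStack, cell_size: float = 1.0) -> DegreeGrid:
    """Overlay the degree grid and index raster cells by grid box."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    rows, cols = stack.valid_indices()
    if rows.size == 0:
        raise ValueError("stack mask is empty")
    lon, lat = stack.transform.cell_center(rows, cols)
    ix = np.floor(lon / cell_size).astype(int)
    iy = np.floor(lat / cell_size).astype(int)
    members: dict[CellId, tuple[np.ndarray, np.ndarray]] = {}
    order = np.lexsort((iy, ix))
    ids = np.column_stack([ix, iy])[order]
    r_s, c_s = rows[order], cols[order]
    boundaries = np.nonzero(np.any(np.diff(ids, axis=0) != 0, axis=1))[0] + 1
    for chunk_ids, chunk_r, chunk_c in zip(
            np.split(ids, boundaries), np.split(r_s, boundaries),
            np.split(c_s, boundaries)):
        members[(int(chunk_ids[0][0]), int(chunk_ids[0][1]))] = (chunk_r, chunk_c)
    cells = sorted(members)
    return DegreeGrid(cell_size=cell_size, cells=cells, members=members)


def filter_cells_by_density(grid: DegreeGrid, density: DensityRaster,
                            min_density: float = 10.0) -> DegreeGrid:
    """Keep grid cells whose mean density strictly exceeds ``min_density``.

    The default 10 individuals/km² screens out cells where the species
    is essentially absent so that CV compares plausible habitat only.
    """
    kept: list[CellId] = []
    members = {}
    for cell in grid.cells:
        r, c = grid.members[cell]
        vals = density.values[r, c]
        vals = vals[np.isfinite(vals)]
        if vals.size and vals.mean() > min_density:
            kept.append(cell)
            members[cell] = grid.members[cell]
    return DegreeGrid(cell_size=grid.cell_size, cells=kept, members=members)


@dataclass
class CVConfig:
    """Cross-validation knobs (scale, absence sampling, model config)."""

    scale: str = "logistic"
    n_random: int = 30
    min_density: float = 10.0
    cell_size: float = 1.0
    seed: int = 0
    refit_for_absences: bool = False
    maxent: MaxentConfig = field(default_factory=MaxentConfig)


@dataclass
class CVResult:
    occurrence_cells: list[dict]
    absence_cells: list[dict]
    t_statistic: float
    p_value: float
    scale: str
    density_series: dict | None = None

    @property
    def occurrence_means(self) -> np.ndarray:
        return np.array([c["mean_predicted"] for c in self.occurrence_cells])

    @property
    def absence_means(self) -> np.ndarray:
        return np.array([c["mean_predicted"] for c in self.absence_cells])

    def as_dict(self) -> dict:
        return {
            "occurrence_cells": [
                {**c, "cell_id": list(c["cell_id"])} for c in self.occurrence_cells
            ],
            "absence_cells": [
                {**c, "cell_id": list(c["cell_id"])} for c in self.absence_cells
            ],
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "scale": self.scale,
        }


def _occupied_cells(occurrences: OccurrenceSet, stack: RasterStack,
                    grid: DegreeGrid) -> tuple[list[CellId], np.ndarray, np.ndarray]:
    """Grid cell of each usable occurrence, plus the kept point indices."""
    row, col, kept = points_to_cells(stack, occurrences)
    lon, lat = stack.transform.cell_center(row, col)
    return grid.assign_points(lon, lat), kept, np.column_stack([row, col])


def _cell_mean_suitability(model: MaxentModel, stack: RasterStack,
                           grid: DegreeGrid, cell: CellId, scale: str) -> float:
    r, c = grid.members[cell]
    covs = np.column_stack([stack.layers[v][r, c] for v in stack.layer_names])
    vals = model.predict_values(covs, scale=scale, all_names=stack.layer_names)
    return float(vals.mean())


def leave_cell_out_scores(occurrences: OccurrenceSet, stack: RasterStack,
                          grid: DegreeGrid, config: CVConfig | None = None
                          ) -> list[dict]:
    """Hold out each occupied retained cell, refit, and score that cell.

    Returns one entry per fold: the cell id, how many points were
    removed, and the refit model's mean suitability over the cell's
    raster cells.  Folds that would leave no training presences are
    skipped with a warning.
    """
    config = config or CVConfig()
    point_cells, kept, _ = _occupied_cells(occurrences, stack, grid)
    retained = set(grid.cells)
    occupied = sorted({c for c in point_cells if c in retained})
    if len({c for c in point_cells}) < 2:
        warnings.warn("occurrences occupy fewer than two grid cells; "
                      "no leave-cell-out folds are possible")
        return []
    results = []
    pts = occurrences.points[kept]
    cell_arr = np.array(point_cells, dtype=int)
    for cell in occupied:
        held = np.all(cell_arr == np.array(cell), axis=1)
        train_pts = pts[~held]
        if train_pts.shape[0] == 0:
            warnings.warn(f"fold {cell} skipped: no training presences remain")
            continue
        train = OccurrenceSet(occurrences.breed, train_pts,
                              occurrences.source_tag)
        model = fit_occurrence_model(stack, train, config.maxent)
        mean_pred = _cell_mean_suitability(model, stack, grid, cell, config.scale)
        results.append({
            "cell_id": cell,
            "n_points_removed": int(held.sum()),
            "mean_predicted": mean_pred,
        })
    return results


def absence_cell_scores(occurrences: OccurrenceSet, stack: RasterStack,
                        grid: DegreeGrid, n_random: int = 30,
                        seed: int = 0, config: CVConfig | None = None,
                        model: MaxentModel | None = None) -> list[dict]:
    """Random pseudo-absence points in each unoccupied retained cell.

    Each unoccupied cell receives ``n_random`` uniform draws over its
    non-missing raster cells (with replacement, scored at cell
    centers), evaluated with the model fitted on ALL occurrences; a
    pre-fitted full-data model may be passed to avoid refitting.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    config = config or CVConfig()
    point_cells, _, _ = _occupied_cells(occurrences, stack, grid)
    occupied = set(point_cells)
    unoccupied = [c for c in grid.cells if c not in occupied]
    rng = np.random.default_rng(seed)
    results = []
    for cell in unoccupied:
        r, c = grid.members[cell]
        if r.size == 0:
            continue
        if model is None or config.refit_for_absences:
            cell_model = fit_occurrence_model(stack, occurrences, config.maxent)
        else:
            cell_model = model
        pick = rng.integers(0, r.size, size=n_random)
        covs = np.column_stack(
            [stack.layers[v][r[pick], c[pick]] for v in stack.layer_names])
        vals = cell_model.predict_values(covs, scale=config.scale,
                                         all_names=stack.layer_names)
        results.append({
            "cell_id": cell,
            "n_random_points": int(n_random),
            "mean_predicted": float(vals.mean()),
        })
    return results


def compare_scores(occurrence_means, absence_means,
                   n_kde: int = 256) -> tuple[float, float, dict | None]:
    """Welch two-sample t-test plus kernel-density series for plotting.

    Welch's unequal-variance form is used because the two groups of
    cell means differ in both size and spread.  Degenerate inputs with
    zero variance in both groups give t = 0, p = 1 when the means agree.
    """
    occ = np.asarray(occurrence_means, dtype=float)
    ab = np.asarray(absence_means, dtype=float)
    if occ.size < 2 or ab.size < 2:
        raise ValueError("each group needs at least two values")
    if np.ptp(occ) == 0 and np.ptp(ab) == 0:
        if occ[0] == ab[0]:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(occ[0] - ab[0]) * np.inf), 0.0
    else:
        res = ttest_ind(occ, ab, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    series = None
    both = np.concatenate([occ, ab])
    if np.ptp(occ) > 0 and np.ptp(ab) > 0:
        try:
            x = np.linspace(both.min() - 0.05, both.max() + 0.05, n_kde)
            series = {
                "x": x,
                "occurrence": gaussian_kde(occ)(x),
                "absence": gaussian_kde(ab)(x),
            }
        except np.linalg.LinAlgError:  # numerically singular group
            series = None
    return t, p, series


def run_grid_cv(stack: RasterStack, occurrences: OccurrenceSet,
                density: DensityRaster, config: CVConfig | None = None
                ) -> CVResult:
    """Full grid CV: build, density-filter, fold, score, compare."""
    config = config or CVConfig()
    grid = build_grid(stack, config.cell_size)
    grid = filter_cells_by_density(grid, density, config.min_density)
    occ_cells = leave_cell_out_scores(occurrences, stack, grid, config)
    full_model = fit_occurrence_model(stack, occurrences, config.maxent)
    abs_cells = absence_cell_scores(occurrences, stack, grid,
                                    n_random=config.n_random,
                                    seed=config.seed, config=config,
                                    model=full_model)
    occ_means = [c["mean_predicted"] for c in occ_cells]
    abs_means = [c["mean_predicted"] for c in abs_cells]
    if len(occ_means) >= 2 and len(abs_means) >= 2:
        t, p, series = compare_scores(occ_means, abs_means)
    else:
        warnings.warn("too few cells for a two-sample comparison")
        t, p, series = float("nan"), float("nan"), None
    return CVResult(occurrence_cells=occ_cells, absence_cells=abs_cells,
                    t_statistic=t, p_value=p, scale=config.scale,
                    density_series=series)
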