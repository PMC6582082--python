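"""Per-region suitable-area accounting and two-breed comparison maps.

Region areas use the spherical cell-area model (cell area depends only
on the grid row's latitude band), so per-region totals add up exactly
to the map-wide figures.  The two-breed comparison is a log₂ ratio of
suitability surfaces with a small additive guard, symmetric in sign
under argument swap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import BinaryMap
from .geodata import RegionMap
from .maxent import SuitabilityMap


@dataclass
class RegionSuitability:
    """Per-region total and suitable areas (km²) with percent suitable."""

    table: pd.DataFrame  # columns: region, total_km2, suitable_km2, percent
    breed: str = ""

    def percents(self) -> dict[str, float]:
        return dict(zip(self.table["region"], self.table["percent"]))


def suitable_area_by_region(binary: BinaryMap, regions: RegionMap,
                            cell_areas_km2: np.ndarray,
                            breed: str = "") -> RegionSuitability:
    """Total and predicted-suitable area per region.

    ``cell_areas_km2`` is the per-grid-row area vector; each cell
    contributes its row's area to its region's total, and to the
    suitable total when the binary map marks it suitable.  Regions with
    zero total area are excluded with a warning.
    """
    labels = regions.labels
    if labels.shape != binary.suitable.shape:
        raise ValueError(
            f"region grid {labels.shape} does not align with "
            f"binary map {binary.suitable.shape}"
        )
    valid = binary.valid if binary.valid is not None else np.ones_like(labels, bool)
    area_grid = np.broadcast_to(
        np.asarray(cell_areas_km2, dtype=float)[:, None], labels.shape)
    rows = []
    for label in sorted(regions.names):
        in_region = (labels == label) & valid
        total = float(area_grid[in_region].sum())
        if total == 0.0:
            warnings.warn(f"region {regions.names[label]!r} has zero area; excluded")
            continue
        suit = float(area_grid[in_region & binary.suitable].sum())
        rows.append({
            "region": regions.names[label],
            "total_km2": total,
            "suitable_km2": suit,
            "percent": 100.0 * suit / total,
        })
    return RegionSuitability(table=pd.DataFrame(rows), breed=breed)


def rank_regions(result: RegionSuitability, top_n: int = 4) -> pd.DataFrame:
    """Regions ordered by percent suitable, descending; ties break on name.

    The default reports the top four regions, the shape in which such
    rankings are usually tabulated; pass a larger ``top_n`` for more.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ordered = result.table.sort_values(
        ["percent", "region"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ordered.head(top_n)


@dataclass
class RatioMap:
    """log₂ suitability ratio between two breeds with a 3-way class label."""

    values: np.ndarray
    classes: np.ndarray  # "+1" A-favored, "-1" B-favored, 0 neutral
    breed_a: str = ""
    breed_b: str = ""
    neutral_band: float = 0.5


def suitability_ratio(map_a: SuitabilityMap, map_b: SuitabilityMap,
                      epsilon: float = 1e-6,
                      neutral_band: float = 0.5) -> RatioMap:
    """Cellwise log₂((a+ε)/(b+ε)) with an A/B/neutral classification.

    ε guards the ratio near zero suitability and bounds the map; cells
    with |log₂ ratio| ≤ neutral_band are called neutral.  Swapping the
    two maps negates every value and swaps the class labels.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("suitability maps are not on the same grid")
    if map_a.scale != map_b.scale:
        raise ValueError(
            f"scale mismatch: {map_a.scale!r} vs {map_b.scale!r}"
        )
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    with np.errstate(invalid="ignore"):
        # difference of logs rather than log of ratio: exact sign
        # antisymmetry under argument swap
        values = np.log2(map_a.values + epsilon) - np.log2(map_b.values + epsilon)
    classes = np.zeros(values.shape, dtype=int)
    classes[values > neutral_band] = 1
    classes[values < -neutral_band] = -1
    classes[~np.isfinite(values)] = 0
    return RatioMap(values=values, classes=classes, breed_a=map_a.breed,
                    breed_b=map_b.breed, neutral_band=neutral_band)
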