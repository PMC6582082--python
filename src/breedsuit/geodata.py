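"""Raster and point I/O, grid alignment, covariate extraction, cell areas.

Rasters are single-band ESRI ASCII grids (``.asc``) on a shared
plate-carrée degree grid with square cells and the origin at the
top-left (north-west) corner.  A stack of covariate layers is described
by a JSON manifest mapping layer names to files.  Occurrence points are
CSV files with a ``lon,lat,breed`` header.

Containment convention: cells are half-open, ``[x, x + w)`` in
longitude and ``(y - w, y]`` in latitude, so a point exactly on a cell
boundary belongs to the cell to its south-east.  This makes point →
cell assignment deterministic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088
DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Affine mapping between grid indices and geographic degrees.

    ``west``/``north`` are the coordinates of the outer corner of cell
    (0, 0); ``cellsize`` is the square cell width in decimal degrees.
    """

    west: float
    north: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")

    def cell_center(self, row, col):
        """Longitude/latitude of a cell center (vectorized)."""
        lon = self.west + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.north - (np.asarray(row) + 0.5) * self.cellsize
        return lon, lat

    def index_of(self, lon, lat):
        """Row/column of the cell containing a point (half-open cells)."""
        col = np.floor((np.asarray(lon) - self.west) / self.cellsize).astype(int)
        row = np.floor((self.north - np.asarray(lat)) / self.cellsize).astype(int)
        return row, col

    def close_to(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )


@dataclass
class RasterStack:
    """Aligned multi-layer environmental grid: the model's background universe.

    All layers share one shape, transform and missing-value mask (the
    union of per-layer nodata masks — the model needs a complete
    covariate vector in every usable cell).
    """

    layers: dict[str, np.ndarray]
    transform: GridTransform
    missing: np.ndarray  # True where a cell is unusable in ANY layer
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("RasterStack needs at least one layer")
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"layer shapes differ: {shapes}")
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.shape:
            raise ValueError(
                f"mask shape {self.missing.shape} != layer shape {self.shape}"
            )
        if not (~self.missing).any():
            raise ValueError("RasterStack has no usable (non-missing) cells")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int((~self.missing).sum())

    def valid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of non-missing cells in row-major order."""
        return np.nonzero(~self.missing)

    def covariate_matrix(self) -> np.ndarray:
        """Non-missing cells × layers matrix, cells in row-major order."""
        rows, cols = self.valid_indices()
        return np.column_stack([self.layers[n][rows, cols] for n in self.layers])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of every non-missing cell center."""
        rows, cols = self.valid_indices()
        return self.transform.cell_center(rows, cols)


@dataclass
class OccurrenceSet:
    """Presence-only records for one breed: (lon, lat) in decimal degrees."""

    breed: str
    points: np.ndarray  # (n, 2) array of (lon, lat)
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (lon, lat)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("occurrence coordinates must be finite")
        lon, lat = self.points[:, 0], self.points[:, 1]
        if ((lon < -180) | (lon > 180)).any() or ((lat < -90) | (lat > 90)).any():
            raise ValueError("coordinates outside lon [-180,180] / lat [-90,90]")

    def __len__(self) -> int:
        return self.points.shape[0]

    def subset(self, index) -> "OccurrenceSet":
        return OccurrenceSet(self.breed, self.points[np.asarray(index)], self.source_tag)


@dataclass
class RegionMap:
    """Integer region labels aligned to a stack, with label → name lookup."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.names:
            self.names = {int(k): f"region_{int(k)}" for k in np.unique(self.labels) if k > 0}


@dataclass
class DensityRaster:
    """Livestock density in individuals/km², aligned to a stack."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_raster(path, values: np.ndarray, transform: GridTransform,
                 missing: np.ndarray | None = None,
                 nodata: float = DEFAULT_NODATA) -> None:
    """Write one layer as an ESRI ASCII grid (rows north → south)."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    out = values.copy()
    if missing is not None:
        out[np.asarray(missing, dtype=bool)] = nodata
    yll = transform.north - nrows * transform.cellsize
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {transform.west!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {transform.cellsize!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.17g")


def read_raster(path) -> tuple[np.ndarray, GridTransform, np.ndarray]:
    """Read an ESRI ASCII grid; returns (values, transform, missing mask)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    transform = GridTransform(
        west=header["xllcorner"],
        north=header["yllcorner"] + nrows * header["cellsize"],
        cellsize=header["cellsize"],
    )
    nodata = header.get("nodata_value")
    missing = np.zeros_like(values, dtype=bool) if nodata is None else values == nodata
    return values, transform, missing


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_raster_stack(stack: RasterStack, out_dir) -> Path:
    """Write every layer plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, arr in stack.layers.items():
        fname = f"{name}.asc"
        write_raster(out_dir / fname, arr, stack.transform, stack.missing)
        entries.append({"name": name, "path": fname})
    manifest = {"crs": stack.crs_tag, "layers": entries}
    manifest_path = out_dir / "stack.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_raster_stack(manifest) -> RasterStack:
    """Load aligned layers from a JSON manifest or a list of (name, path).

    Any cell flagged nodata in one layer is treated as missing in all
    layers (union mask).  Shape or transform mismatches raise with the
    offending layer named.
    """
    crs_tag = "EPSG:4326"
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        spec = json.loads(manifest_path.read_text())
        crs_tag = spec.get("crs", crs_tag)
        base = manifest_path.parent
        pairs = [(e["name"], base / e["path"]) for e in spec["layers"]]
    else:
        pairs = [(name, Path(p)) for name, p in manifest]
    if not pairs:
        raise ValueError("empty stack manifest")
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate layer names in manifest: {names}")

    layers: dict[str, np.ndarray] = {}
    ref_name = ref_transform = None
    masks = []
    for name, path in pairs:
        values, transform, missing = read_raster(path)
        if ref_transform is None:
            ref_name, ref_transform = name, transform
            ref_shape = values.shape
        else:
            if values.shape != ref_shape:
                raise ValueError(
                    f"layer {name!r} shape {values.shape} does not match "
                    f"layer {ref_name!r} shape {ref_shape}"
                )
            if not transform.close_to(ref_transform):
                raise ValueError(
                    f"layer {name!r} transform {transform} does not match "
                    f"layer {ref_name!r} transform {ref_transform}"
                )
        layers[name] = values
        masks.append(missing)
    union = np.logical_or.reduce(masks)
    return RasterStack(layers=layers, transform=ref_transform,
                       missing=union, crs_tag=crs_tag)


# ---------------------------------------------------------------------------
# Point I/O


def write_occurrences(occ: OccurrenceSet, path) -> None:
    df = pd.DataFrame({
        "lon": occ.points[:, 0],
        "lat": occ.points[:, 1],
        "breed": occ.breed,
    })
    df.to_csv(path, index=False)


def read_occurrences(path, breed: str | None = None) -> OccurrenceSet:
    """Read a ``lon,lat,breed`` CSV; optionally filter to one breed."""
    df = pd.read_csv(path)
    required = {"lon", "lat", "breed"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: occurrence CSV needs columns {sorted(required)}")
    if breed is not None:
        df = df[df["breed"] == breed]
        label = breed
    else:
        uniq = df["breed"].unique()
        if len(uniq) > 1:
            raise ValueError(
                f"{path}: multiple breeds {list(uniq)}; pass breed= to select one"
            )
        label = str(uniq[0]) if len(uniq) else "unknown"
    return OccurrenceSet(label, df[["lon", "lat"]].to_numpy(float), source_tag=str(path))


# ---------------------------------------------------------------------------
# Extraction and areas


def extract_covariates(stack: RasterStack,
                       points: OccurrenceSet | np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Covariate values at each point's containing cell.

    Points outside the stack extent or on missing cells are dropped.
    Returns ``(matrix, kept_index)`` where rows of the n_kept × n_layers
    matrix follow ``kept_index`` (indices into the input point list).
    """
    pts = points.points if isinstance(points, OccurrenceSet) else np.atleast_2d(points)
    if pts.shape[0] == 0:
        return np.empty((0, len(stack.layers))), np.empty(0, dtype=int)
    row, col = stack.transform.index_of(pts[:, 0], pts[:, 1])
    inside = (row >= 0) & (row < stack.n_rows) & (col >= 0) & (col < stack.n_cols)
    keep = inside.copy()
    keep[inside] &= ~stack.missing[row[inside], col[inside]]
    kept_index = np.nonzero(keep)[0]
    if kept_index.size == 0:
        warnings.warn("all points fell outside the stack or on missing cells")
        return np.empty((0, len(stack.layers))), kept_index
    r, c = row[kept_index], col[kept_index]
    matrix = np.column_stack([stack.layers[n][r, c] for n in stack.layers])
    return matrix, kept_index


def points_to_cells(stack: RasterStack,
                    points: OccurrenceSet | np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(row, col, kept_index) of the cells containing each usable point."""
    pts = points.points if isinstance(points, OccurrenceSet) else np.atleast_2d(points)
    row, col = stack.transform.index_of(pts[:, 0], pts[:, 1])
    inside = (row >= 0) & (row < stack.n_rows) & (col >= 0) & (col < stack.n_cols)
    keep = inside.copy()
    keep[inside] &= ~stack.missing[row[inside], col[inside]]
    kept = np.nonzero(keep)[0]
    return row[kept], col[kept], kept


def cell_areas_by_row(stack: RasterStack) -> np.ndarray:
    """Spherical area in km² of one cell in each grid row.

    For a cell with latitude bounds φ₁ < φ₂ and longitude width Δλ the
    area is R²·Δλ_rad·(sin φ₂ − sin φ₁) with R = 6371.0088 km, which
    decreases monotonically with |latitude|.
    """
    cs = stack.transform.cellsize
    rows = np.arange(stack.n_rows)
    lat_top = stack.transform.north - rows * cs
    lat_bot = lat_top - cs
    if lat_top.max() > 90 + 1e-12 or lat_bot.min() < -90 - 1e-12:
        raise ValueError(
            f"latitude bounds [{lat_bot.min()}, {lat_top.max()}] outside [-90, 90]"
        )
    dlam = math.radians(cs)
    return (EARTH_RADIUS_KM ** 2) * dlam * (
        np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot))
    )
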