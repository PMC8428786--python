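"""Grid and point data model plus raster / table I/O.

The package works on regular north-up lon/lat grids.  A :class:`GridSpec`
pins down the geometry once; every raster product (climate layers,
suitability maps, class maps, region masks) carries the same spec so that
stacks are only combinable when their grids match exactly.

Conventions
-----------
* ``origin`` is the (lon, lat) of the **north-west corner** of the grid
  (the outer edge, not the first cell centre); rows run north to south.
* Point-to-cell lookup uses half-open intervals ``[edge, edge + cell_size)``
  so a point sitting exactly on a cell's NW corner belongs to that cell.
* Nodata is represented by a boolean mask shared by all layers of a stack;
  on disk the sentinel is -9999 for float rasters and 255 for byte rasters.

Rasters are plain GeoTIFFs: georeferencing is stored in the standard
ModelPixelScale / ModelTiepoint tags, the nodata value in the GDAL_NODATA
tag, so files interoperate with GDAL-based tooling.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    DataError,
    ExtentError,
    GeometryError,
    NamingError,
    ValidationError,
)

PRESENCE = "presence"
BACKGROUND = "background"

FLOAT_NODATA = -9999.0
BYTE_NODATA = 255

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKey directory: geographic model, pixel-is-area, WGS84 (EPSG 4326)
_WGS84_GEOKEYS = (
    1, 1, 0, 3,
    1024, 0, 1, 2,      # GTModelType = geographic
    1025, 0, 1, 1,      # GTRasterType = PixelIsArea
    2048, 0, 1, 4326,   # GeographicType = WGS84
)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular north-up lon/lat grid with square cells."""

    n_rows: int
    n_cols: int
    origin: tuple[float, float]  # (lon, lat) of the NW corner
    cell_size: float             # degrees per cell
    crs_tag: str = "WGS84"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValidationError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_edges(self) -> np.ndarray:
        return self.origin[0] + self.cell_size * np.arange(self.n_cols + 1)

    def lat_edges(self) -> np.ndarray:
        return self.origin[1] - self.cell_size * np.arange(self.n_rows + 1)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) centre coordinates as 1-D arrays of length n_cols / n_rows."""
        lon0, lat0 = self.origin
        lons = lon0 + self.cell_size * (np.arange(self.n_cols) + 0.5)
        lats = lat0 - self.cell_size * (np.arange(self.n_rows) + 0.5)
        return lons, lats

    def locate(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open cell convention.

        Returns ``(row, col, inside)`` where ``inside`` flags points that
        fall within the grid extent.  Rows count from the north.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - lat) / self.cell_size).astype(int)
        # a point exactly on the northern/western edge belongs to row/col 0;
        # exactly on the southern/eastern outer edge is outside
        on_north = lat == self.origin[1]
        row = np.where(on_north, 0, row)
        on_west = lon == self.origin[0]
        col = np.where(on_west, 0, col)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return row, col, inside

    def __eq__(self, other) -> bool:  # exact geometry match required to combine
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.origin == other.origin
            and self.cell_size == other.cell_size
            and self.crs_tag == other.crs_tag
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class ClimateStack:
    """Named raster layers on one shared grid with a shared nodata mask."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise NamingError("duplicate layer names")
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise GeometryError("nodata mask shape does not match grid")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise GeometryError(
                    f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}"
                )
            if not np.all(np.isfinite(arr[~self.nodata_mask])):
                raise DataError(f"layer {name!r} has non-finite values off-mask")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def to_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Valid cells as a (n_valid, n_layers) matrix in layer order."""
        names = list(names) if names is not None else self.names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise NamingError(f"stack is missing layers: {missing}")
        valid = ~self.nodata_mask
        return np.column_stack([self.layers[n][valid] for n in names])

    def replace_layers(self, layers: Mapping[str, np.ndarray]) -> "ClimateStack":
        return ClimateStack(self.grid, dict(layers), self.nodata_mask.copy())


@dataclass
class OccurrenceSet:
    """Labelled point records: observed presences and background pseudo-absences."""

    points: pd.DataFrame  # columns lon, lat, label
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"lon", "lat", "label"}
        if not required.issubset(self.points.columns):
            raise ValidationError(f"occurrence table needs columns {sorted(required)}")
        bad = set(self.points["label"].unique()) - {PRESENCE, BACKGROUND}
        if bad:
            raise ValidationError(f"unknown occurrence labels: {sorted(bad)}")
        self.points = self.points.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, lon, lat, label, provenance: str = "") -> "OccurrenceSet":
        if np.isscalar(label) or isinstance(label, str):
            label = [label] * len(lon)
        return cls(
            pd.DataFrame({"lon": lon, "lat": lat, "label": list(label)}),
            provenance=provenance,
        )

    @property
    def n_presence(self) -> int:
        return int((self.points["label"] == PRESENCE).sum())

    @property
    def n_background(self) -> int:
        return int((self.points["label"] == BACKGROUND).sum())

    def subset(self, index) -> "OccurrenceSet":
        return OccurrenceSet(
            self.points.loc[index].reset_index(drop=True), provenance=self.provenance
        )

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RegionMask:
    """Integer-labelled regions on a grid; 0 means outside the study area."""

    grid: GridSpec
    region_id: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.region_id.shape != self.grid.shape:
            raise GeometryError("region raster shape does not match grid")
        present = set(np.unique(self.region_id)) - {0}
        unknown = present - set(self.region_names)
        if unknown:
            raise ValidationError(f"region ids without names: {sorted(unknown)}")

    @property
    def ids(self) -> list[int]:
        return sorted(set(np.unique(self.region_id)) - {0})


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile backend)
# ---------------------------------------------------------------------------

def _geo_extratags(grid: GridSpec, nodata) -> list[tuple]:
    lon0, lat0 = grid.origin
    cs = grid.cell_size
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, lon0, lat0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def write_map(
    values: np.ndarray,
    grid: GridSpec,
    path,
    dtype_tag: str = "float32",
    nodata_mask: np.ndarray | None = None,
) -> None:
    """Write a single 2-D array as a georeferenced GeoTIFF.

    ``dtype_tag`` is ``"float32"`` (nodata sentinel -9999) or ``"uint8"``
    (sentinel 255).  Cells under ``nodata_mask`` are written as the sentinel.
    """
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise GeometryError(f"array shape {values.shape} != grid {grid.shape}")
    if dtype_tag in ("float32", "float64"):
        sentinel: float | int = FLOAT_NODATA
        out = values.astype(dtype_tag)
    elif dtype_tag in ("uint8", "byte"):
        sentinel = BYTE_NODATA
        out = values.astype(np.uint8)
    else:
        raise ValidationError(f"unsupported dtype_tag {dtype_tag!r}")
    if nodata_mask is not None:
        out = out.copy()
        out[np.asarray(nodata_mask, dtype=bool)] = sentinel
    try:
        tifffile.imwrite(
            path,
            out,
            photometric="minisblack",
            extratags=_geo_extratags(grid, sentinel),
        )
    except OSError as exc:  # pragma: no cover - I/O environment dependent
        raise DataError(f"failed to write raster {path}: {exc}") from exc


def _read_page(path):
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = tif.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
    except OSError as exc:
        raise DataError(f"failed to read raster {path}: {exc}") from exc
    return data, tags


def _grid_from_tags(shape: tuple[int, int], tags: dict) -> GridSpec:
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise DataError("raster lacks GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise GeometryError("only square cells are supported")
    tie = tags[_TAG_TIEPOINT]
    # tiepoint maps raster (i, j) = (0, 0) to model (lon, lat)
    lon0 = tie[3] - tie[0] * sx
    lat0 = tie[4] + tie[1] * sy
    return GridSpec(shape[0], shape[1], (lon0, lat0), sx)


def read_map(path) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read a single-band GeoTIFF -> (values, grid, nodata_mask)."""
    data, tags = _read_page(path)
    if data.ndim != 2:
        raise DataError(f"{path}: expected a single-band raster")
    grid = _grid_from_tags(data.shape, tags)
    nodata = tags.get(_TAG_GDAL_NODATA)
    if nodata is not None:
        sentinel = float(nodata)
        mask = (
            np.isclose(data.astype(float), sentinel)
            if np.issubdtype(data.dtype, np.floating)
            else data == int(sentinel)
        )
    else:
        mask = np.zeros(data.shape, dtype=bool)
    return data, grid, mask


def read_stack(paths: Sequence, names: Sequence[str]) -> ClimateStack:
    """Assemble single-band rasters into a :class:`ClimateStack`.

    All rasters must share the exact grid geometry; the stack's nodata mask
    is the union of the per-layer masks.
    """
    paths = list(paths)
    names = list(names)
    if len(set(names)) != len(names):
        raise NamingError("duplicate layer names")
    if not paths:
        raise ValidationError("read_stack needs at least one raster")
    if len(paths) == 1 and len(names) > 1:
        return _read_multiband_stack(paths[0], names)
    if len(paths) != len(names):
        raise ValidationError("paths and names must have equal length")
    layers: dict[str, np.ndarray] = {}
    grid: GridSpec | None = None
    mask: np.ndarray | None = None
    for path, name in zip(paths, names):
        data, g, m = read_map(path)
        if grid is None:
            grid, mask = g, m.copy()
        else:
            if g != grid:
                raise GeometryError(
                    f"raster {path} geometry does not match the first raster"
                )
            mask |= m
        layers[name] = data.astype(float)
    assert grid is not None and mask is not None
    for name in layers:  # sentinel values under the mask are not data
        layers[name] = np.where(mask, 0.0, layers[name])
    return ClimateStack(grid, layers, mask)


def _read_multiband_stack(path, names: Sequence[str]) -> ClimateStack:
    """One multiband GeoTIFF, one band per variable in ``names`` order."""
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            tags = {t.code: t.value for t in tif.pages[0].tags.values()}
    except OSError as exc:
        raise DataError(f"failed to read raster {path}: {exc}") from exc
    if data.ndim != 3 or data.shape[0] != len(names):
        raise DataError(
            f"{path}: expected {len(names)} bands, found shape {data.shape}"
        )
    grid = _grid_from_tags(data.shape[1:], tags)
    nodata = tags.get(_TAG_GDAL_NODATA)
    if nodata is not None:
        mask = np.isclose(data.astype(float), float(nodata)).any(axis=0)
    else:
        mask = np.zeros(data.shape[1:], dtype=bool)
    layers = {
        name: np.where(mask, 0.0, data[k].astype(float))
        for k, name in enumerate(names)
    }
    return ClimateStack(grid, layers, mask)


def write_stack(stack: ClimateStack, directory, prefix: str = "") -> dict[str, str]:
    """Write each layer as ``<directory>/<prefix><name>.tif``; returns paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, arr in stack.layers.items():
        path = directory / f"{prefix}{name}.tif"
        write_map(arr, stack.grid, path, "float32", stack.nodata_mask)
        out[name] = str(path)
    return out


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

def read_occurrences(path, provenance: str | None = None) -> OccurrenceSet:
    """Read a ``lon,lat[,label]`` CSV; a missing label column means presence."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"lon", "lat"}.issubset(df.columns):
        raise ValidationError(f"{path}: occurrence CSV must have lon,lat columns")
    if "label" not in df.columns:
        df["label"] = PRESENCE
    return OccurrenceSet(
        df[["lon", "lat", "label"]],
        provenance=provenance if provenance is not None else str(path),
    )


def write_occurrences(occ: OccurrenceSet, path) -> None:
    occ.points[["lon", "lat", "label"]].to_csv(
        path, index=False, quoting=csv.QUOTE_MINIMAL
    )


def extract_values(
    stack: ClimateStack, occ: OccurrenceSet
) -> tuple[pd.DataFrame, np.ndarray, list[int]]:
    """Sample stack layers at occurrence points.

    Returns ``(X, y, dropped)``: a design matrix with one column per layer,
    a 0/1 label vector (presence = 1), and the row indices of points that
    hit nodata cells and were dropped.  Points outside the grid extent are
    an error.
    """
    lon = occ.points["lon"].to_numpy()
    lat = occ.points["lat"].to_numpy()
    row, col, inside = stack.grid.locate(lon, lat)
    if not inside.all():
        offenders = np.flatnonzero(~inside).tolist()
        raise ExtentError(f"points outside grid extent at rows {offenders}")
    on_nodata = stack.nodata_mask[row, col]
    dropped = np.flatnonzero(on_nodata).tolist()
    keep = ~on_nodata
    data = {
        name: arr[row[keep], col[keep]] for name, arr in stack.layers.items()
    }
    X = pd.DataFrame(data)
    y = (occ.points["label"].to_numpy()[keep] == PRESENCE).astype(int)
    return X, y, dropped


def thin_occurrences(
    occ: OccurrenceSet, grid: GridSpec, seed: int | np.random.Generator = 0
) -> OccurrenceSet:
    """Thin presence points to at most one per grid cell.

    Within a cell the survivor is chosen uniformly at random under the seed;
    background points are passed through untouched.  Applying the operation
    twice is a no-op.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    pts = occ.points
    is_pres = (pts["label"] == PRESENCE).to_numpy()
    lon = pts["lon"].to_numpy()
    lat = pts["lat"].to_numpy()
    row, col, inside = grid.locate(lon, lat)
    if not inside[is_pres].all():
        raise ExtentError("presence points outside grid extent")
    keep = np.zeros(len(pts), dtype=bool)
    keep[~is_pres] = True
    cells: dict[tuple[int, int], list[int]] = {}
    for i in np.flatnonzero(is_pres):
        cells.setdefault((int(row[i]), int(col[i])), []).append(i)
    for members in cells.values():
        keep[members[int(rng.integers(len(members)))] if len(members) > 1 else members[0]] = True
    return occ.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Region masks
# ---------------------------------------------------------------------------

def regions_from_geojson(source, grid: GridSpec) -> RegionMask:
    """Rasterize a GeoJSON FeatureCollection of polygons onto the grid.

    Features are assigned ids 1..n in file order; a feature's region name is
    its ``name`` property (falling back to ``region_<id>``).  A cell belongs
    to a region when its centre falls inside the polygon; later features win
    overlaps.
    """
    import shapely
    from shapely.geometry import shape as shapely_shape

    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = source
    features = doc.get("features", [])
    if not features:
        raise DataError("GeoJSON contains no features")
    lons, lats = grid.cell_centers()
    lon_grid, lat_grid = np.meshgrid(lons, lats)
    region_id = np.zeros(grid.shape, dtype=int)
    names: dict[int, str] = {}
    for k, feat in enumerate(features, start=1):
        geom = shapely_shape(feat["geometry"])
        inside = shapely.contains_xy(geom, lon_grid.ravel(), lat_grid.ravel())
        region_id[inside.reshape(grid.shape)] = k
        names[k] = feat.get("properties", {}).get("name", f"region_{k}")
    return RegionMask(grid, region_id, names)


def regions_from_raster(path, region_names: Mapping[int, str] | None = None) -> RegionMask:
    """Read a label raster (byte GeoTIFF) as a :class:`RegionMask`."""
    data, grid, mask = read_map(path)
    region_id = data.astype(int)
    region_id[mask] = 0
    ids = sorted(set(np.unique(region_id)) - {0})
    if region_names is None:
        region_names = {i: f"region_{i}" for i in ids}
    return RegionMask(grid, region_id, dict(region_names))


def write_regions(mask: RegionMask, path) -> None:
    write_map(mask.region_id, mask.grid, path, "uint8", mask.region_id == 0)
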