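"""Shared grid/vector data model and file I/O.

All layers in the pipeline — ranges, richness, predictors — move through a
single raster data model, :class:`RasterGrid`.  Rasters are stored on disk
as ESRI ASCII grids (``.asc``), a plain-text single-band format whose
header carries exactly the georeferencing this model needs; the CRS tag is
written to a ``.prj`` sidecar.  Vector layers (biomes, mountain ranges,
study-area mask) are GeoJSON FeatureCollections handled through shapely.

Coordinate convention
---------------------
Rasters are row-major with row 0 northernmost.  Cell ``(r, c)`` covers the
half-open square ``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]``
where ``(x0, y0)`` is the *top-left corner* of the grid and ``s`` the cell
size.  A point maps to the unique cell containing it; points on the eastern
or southern outer boundary fall outside the grid.  This one rule is shared
by thinning, rasterization and raster sampling.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely import make_valid

logger = logging.getLogger("rangestack")

#: columns of the driver-table CSV, in file order
DRIVER_TABLE_COLUMNS = [
    "group", "predictor", "form", "slope", "slope_linear_term",
    "z_value", "p_stars", "AIC", "D2", "D2_adjusted", "top_d2", "failed",
]


class ConfigurationError(ValueError):
    """Bad user configuration: missing columns, attributes or files."""


class AlignmentError(ValueError):
    """Two rasters that must share a grid do not."""


# ---------------------------------------------------------------------------
# RasterGrid
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values
        2-D array of cell values, row 0 northernmost.
    origin_x, origin_y
        Coordinates of the *top-left corner* of the grid (degrees or km,
        per ``crs_tag``).
    cell_size
        Cell edge length, same units as the origin; cells are square.
    nodata
        Sentinel for invalid cells.  Must not collide with valid values.
    crs_tag
        Free-form CRS identifier; the synthetic pipeline uses ``local-km``
        (flat, Euclidean) and real-data mode ``wgs84``.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = -9999.0
    crs_tag: str = "local-km"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("RasterGrid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- shape ------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- masks ------------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        vals = self.values
        if np.issubdtype(vals.dtype, np.floating):
            return ~(np.isnan(vals) | (vals == self.nodata))
        return vals != self.nodata

    def masked(self) -> np.ndarray:
        """Float copy with nodata cells replaced by NaN."""
        out = self.values.astype(float, copy=True)
        out[~self.valid_mask()] = np.nan
        return out

    # -- georeferencing ---------------------------------------------------
    def aligned_with(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        """Exact-grid equality: origin, cell size and shape all match."""
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=tol)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=tol)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=0, abs_tol=tol)
        )

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a point to its (row, col), or None if outside the grid.

        Uses the half-open cell convention documented in the module
        docstring: west/top edges belong to a cell, east/bottom do not.
        """
        col = math.floor((x - self.origin_x) / self.cell_size)
        row = math.floor((self.origin_y - y) / self.cell_size)
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) 2-D arrays of all cell-centre coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.origin_x + (cols + 0.5) * self.cell_size
        ys = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def sample(self, x: float, y: float) -> float | None:
        """Value of the cell containing (x, y); None if outside or nodata."""
        rc = self.point_to_cell(x, y)
        if rc is None:
            return None
        val = self.values[rc]
        if not self.valid_mask()[rc]:
            return None
        return float(val)

    def copy_with(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """New grid on the same georeferencing with different values."""
        return RasterGrid(
            values=np.asarray(values),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            nodata=self.nodata if nodata is None else nodata,
            crs_tag=self.crs_tag,
        )


def require_aligned(grids: Mapping[str, RasterGrid]) -> None:
    """Raise :class:`AlignmentError` naming the first misaligned grid."""
    items = list(grids.items())
    ref_name, ref = items[0]
    for name, g in items[1:]:
        if not ref.aligned_with(g):
            raise AlignmentError(f"raster '{name}' is not aligned with '{ref_name}'")


# ---------------------------------------------------------------------------
# Raster file I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster with a ``.prj`` CRS sidecar."""
    path = Path(path)
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        vals = grid.values.astype(float, copy=True)
        vals[np.isnan(vals)] = grid.nodata
        np.savetxt(fh, vals, fmt="%.17g")
    path.with_suffix(".prj").write_text(grid.crs_tag + "\n")


def read_raster(path: str | Path, default_nodata: float = -9999.0) -> RasterGrid:
    """Read an ESRI ASCII raster.

    A missing ``NODATA_value`` header triggers a warning and adopts
    ``default_nodata``, mirroring rasters shipped without a nodata tag.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: empty or truncated ASCII grid")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing raster header field '{key}'")
        if "nodata_value" not in header:
            warnings.warn(
                f"{path}: no NODATA_value tag; adopting {default_nodata}",
                stacklevel=2,
            )
            header["nodata_value"] = default_nodata
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({n_rows}, {n_cols}); multi-band or malformed file"
        )
    prj = path.with_suffix(".prj")
    crs_tag = prj.read_text().strip() if prj.exists() else "local-km"
    return RasterGrid(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=header["nodata_value"],
        crs_tag=crs_tag,
    )


# ---------------------------------------------------------------------------
# Occurrence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced species observation."""

    species_id: str
    lon: float
    lat: float
    activity: str  # "diurnal" | "nocturnal"
    endemic: bool
    source: str = ""

    def __post_init__(self) -> None:
        if self.activity not in ("diurnal", "nocturnal"):
            raise ValueError(
                f"activity must be 'diurnal' or 'nocturnal', got {self.activity!r}"
            )
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")


@dataclass
class RejectionLog:
    """Bookkeeping for record cleaning; accepted + rejected = input rows."""

    input_rows: int = 0
    missing_coords: int = 0
    out_of_range: int = 0
    bad_activity: int = 0
    duplicates: int = 0
    accepted: int = 0

    @property
    def rejected(self) -> int:
        return self.missing_coords + self.out_of_range + self.bad_activity + self.duplicates


DEFAULT_COLUMN_MAP = {
    "species_id": "species_id",
    "lon": "lon",
    "lat": "lat",
    "activity": "activity",
    "endemic": "endemic",
    "source": "source",
}

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _parse_bool(raw: object) -> bool:
    if isinstance(raw, bool):
        return raw
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"unparseable boolean: {raw!r}")


def read_occurrence_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[OccurrenceRecord], RejectionLog]:
    """Read an occurrence CSV, cleaning as it goes.

    Rows with missing or unparseable coordinates, out-of-range lon/lat, or
    an unknown activity label are excluded and counted in the returned
    :class:`RejectionLog`.  Exact duplicates on (species_id, lon, lat) are
    removed, keeping the first.  Valid rows are returned in file order.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"occurrence file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    log = RejectionLog()
    records: list[OccurrenceRecord] = []
    seen: set[tuple[str, float, float]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return [], log  # empty file
        for role in ("species_id", "lon", "lat", "activity", "endemic"):
            if cmap[role] not in reader.fieldnames:
                raise ConfigurationError(
                    f"mandatory column '{cmap[role]}' (for {role}) missing from {path}"
                )
        has_source = cmap["source"] in reader.fieldnames
        for row in reader:
            log.input_rows += 1
            try:
                lon = float(row[cmap["lon"]])
                lat = float(row[cmap["lat"]])
            except (TypeError, ValueError):
                log.missing_coords += 1
                continue
            if math.isnan(lon) or math.isnan(lat):
                log.missing_coords += 1
                continue
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                log.out_of_range += 1
                continue
            activity = str(row[cmap["activity"]]).strip().lower()
            if activity not in ("diurnal", "nocturnal"):
                log.bad_activity += 1
                continue
            species = str(row[cmap["species_id"]]).strip()
            key = (species, lon, lat)
            if key in seen:
                log.duplicates += 1
                continue
            seen.add(key)
            records.append(
                OccurrenceRecord(
                    species_id=species,
                    lon=lon,
                    lat=lat,
                    activity=activity,
                    endemic=_parse_bool(row[cmap["endemic"]]),
                    source=str(row.get(cmap["source"], "") or "") if has_source else "",
                )
            )
            log.accepted += 1
    logger.info(
        "read %d occurrence rows from %s: %d accepted, %d rejected "
        "(%d missing coords, %d out of range, %d bad activity, %d duplicates)",
        log.input_rows, path, log.accepted, log.rejected,
        log.missing_coords, log.out_of_range, log.bad_activity, log.duplicates,
    )
    return records, log


def write_occurrence_table(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    """Write records in the same CSV schema :func:`read_occurrence_table` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_id", "lon", "lat", "activity", "endemic", "source"])
        for r in records:
            writer.writerow(
                [r.species_id, repr(r.lon), repr(r.lat), r.activity,
                 str(r.endemic).lower(), r.source]
            )


# ---------------------------------------------------------------------------
# Polygon layers
# ---------------------------------------------------------------------------

@dataclass
class PolygonLayer:
    """A list of (geometry, attributes) features, e.g. biomes or mountains."""

    features: list[tuple[BaseGeometry, dict]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [geom for geom, _ in self.features]

    def attribute(self, name: str) -> list:
        return [attrs[name] for _, attrs in self.features]

    def union(self) -> BaseGeometry:
        from shapely.ops import unary_union

        return unary_union(self.geometries())


def check_non_overlapping(layer: PolygonLayer, tol: float = 1e-6) -> None:
    """Raise if any two features overlap by more than ``tol`` (area units).

    Biome mosaics must partition the study area; shared borders are fine,
    interior overlaps are not.
    """
    geoms = layer.geometries()
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            inter = geoms[i].intersection(geoms[j])
            if inter.area > tol:
                raise ValueError(
                    f"polygon features {i} and {j} overlap by area {inter.area:g}"
                )


def read_polygon_layer(
    path: str | Path,
    required_attr: str | None = None,
    overlap_tol: float | None = None,
) -> PolygonLayer:
    """Read a GeoJSON FeatureCollection into a :class:`PolygonLayer`.

    Geometries are validated and repaired (``make_valid``); zero-area
    features are dropped with a warning.  Every surviving feature must
    carry ``required_attr``.  If ``overlap_tol`` is given, features are
    additionally checked for mutual non-overlap (biome mosaics).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"polygon file not found: {path}")
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    layer = PolygonLayer()
    for idx, feat in enumerate(doc.get("features", [])):
        attrs = dict(feat.get("properties") or {})
        if required_attr is not None and required_attr not in attrs:
            raise ConfigurationError(
                f"{path}: feature {idx} missing required attribute '{required_attr}'"
            )
        geom = make_valid(geom_shape(feat["geometry"]))
        if geom.area == 0:
            warnings.warn(
                f"{path}: feature {idx} has zero area after repair; dropped",
                stacklevel=2,
            )
            logger.warning("dropped zero-area feature %d from %s", idx, path)
            continue
        layer.features.append((geom, attrs))
    if overlap_tol is not None:
        check_non_overlapping(layer, overlap_tol)
    return layer


def write_polygon_layer(layer: PolygonLayer, path: str | Path) -> None:
    """Write features as a GeoJSON FeatureCollection."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": geom_mapping(geom),
                "properties": attrs,
            }
            for geom, attrs in layer.features
        ],
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# Driver table I/O
# ---------------------------------------------------------------------------

def write_driver_table(table, path: str | Path) -> None:
    """Write a driver table (or its DataFrame) as CSV in the fixed schema."""
    frame = table.to_frame() if hasattr(table, "to_frame") else table
    frame = frame.reindex(columns=DRIVER_TABLE_COLUMNS)
    frame.to_csv(path, index=False)


def read_driver_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
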