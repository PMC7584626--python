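"""Hull-based species range construction.

A species' range is approximated by its extent of occurrence, built
biome by biome: a convex hull around the species' observations within
each biome (or a 50-km buffer where the hull is degenerate), clipped to
the biome polygon, unioned across biomes, rasterized on the analysis
grid, and finally trimmed to the species' temperature envelope — the
[2.5th, 97.5th] percentile interval of annual mean temperature at its
occurrence sites.  The envelope step removes climatic outlier area that
the hull geometry alone would include.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .geodata import OccurrenceRecord, PolygonLayer, RasterGrid

logger = logging.getLogger("rangestack")

EARTH_RADIUS_KM = 6371.0088

RANGE_NODATA = -1


@dataclass
class RangeConfig:
    """Tunables of range construction.

    buffer_radius_km : radius of the disk drawn around degenerate
        (point-like or collinear) observation sets, default 50 km.
    q_low, q_high : temperature-envelope percentiles, default 2.5/97.5.
    clip_to_biome : clip each per-biome hull/buffer to its biome polygon
        so a range cannot leak into an unoccupied biome.
    quad_segs : circle-approximation segments per quadrant for buffers.
    """

    buffer_radius_km: float = 50.0
    q_low: float = 2.5
    q_high: float = 97.5
    clip_to_biome: bool = True
    quad_segs: int = 16


@dataclass(frozen=True)
class TemperatureEnvelope:
    """Percentile interval of occurrence-site temperatures (degC)."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if self.t_low > self.t_high:
            raise ValueError("t_low must not exceed t_high")

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        return (t >= self.t_low) & (t <= self.t_high)


@dataclass
class SpeciesRange:
    """A species' polygon range plus its raster realization."""

    species_id: str
    polygons: list[BaseGeometry]
    envelope: TemperatureEnvelope
    raster: RasterGrid

    @property
    def polygon_union(self) -> BaseGeometry:
        return unary_union(self.polygons)

    @property
    def n_cells(self) -> int:
        return int((self.raster.values == 1).sum())


# ---------------------------------------------------------------------------
# Convex hulls and degenerate buffers
# ---------------------------------------------------------------------------

def convex_hull(points: Sequence[tuple[float, float]]) -> tuple[BaseGeometry, bool]:
    """Minimal convex polygon around ``points``.

    Returns ``(geometry, degenerate)``.  The hull is degenerate — a point
    or segment of zero area — when there are fewer than three distinct
    points or all points are collinear; callers should then fall back to
    :func:`buffer_degenerate`.
    """
    if len(points) == 0:
        raise ValueError("convex_hull of empty point set")
    hull = MultiPoint([Point(p) for p in points]).convex_hull
    return hull, hull.area == 0


def _aeqd_forward(lon, lat, lon0, lat0):
    """Spherical azimuthal-equidistant projection, km on the tangent plane."""
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c == 0, 1.0, c / np.sin(c))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def _aeqd_inverse(x, y, lon0, lat0):
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    rho = np.hypot(x, y)
    c = rho
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.where(
            rho == 0,
            phi0,
            np.arcsin(cos_c * math.sin(phi0) + np.where(rho == 0, 0, y * sin_c * math.cos(phi0) / np.where(rho == 0, 1, rho))),
        )
        lam = lam0 + np.arctan2(
            x * sin_c, rho * cos_c * math.cos(phi0) - y * sin_c * math.sin(phi0)
        )
    return np.degrees(lam), np.degrees(phi)


def buffer_degenerate(
    points: Sequence[tuple[float, float]],
    radius_km: float = 50.0,
    crs_tag: str = "local-km",
    quad_segs: int = 16,
) -> Polygon:
    """Disk/stadium buffer around a degenerate observation set.

    In the flat ``local-km`` CRS the buffer is Euclidean.  In ``wgs84``
    mode the point set is projected through a spherical azimuthal
    equidistant projection centred on its centroid, buffered in km there,
    and projected back, so the radius is metric.
    """
    if radius_km <= 0:
        raise ValueError("buffer radius must be positive")
    if len(points) == 0:
        raise ValueError("buffer of empty point set")
    hull, _ = convex_hull(points)
    if crs_tag == "wgs84":
        lon0, lat0 = hull.centroid.x, hull.centroid.y
        coords = np.asarray(shapely.get_coordinates(hull), dtype=float)
        px, py = _aeqd_forward(coords[:, 0], coords[:, 1], lon0, lat0)
        planar = (
            Point(px[0], py[0]) if len(px) == 1
            else LineString(np.column_stack([px, py])).convex_hull
        )
        buffered = planar.buffer(radius_km, quad_segs=quad_segs)
        bx, by = np.asarray(buffered.exterior.coords).T
        blon, blat = _aeqd_inverse(bx, by, lon0, lat0)
        return Polygon(np.column_stack([blon, blat]))
    return hull.buffer(radius_km, quad_segs=quad_segs)


# ---------------------------------------------------------------------------
# Temperature envelope
# ---------------------------------------------------------------------------

def temperature_envelope(
    records: Sequence[OccurrenceRecord],
    temp_raster: RasterGrid,
    q_low: float = 2.5,
    q_high: float = 97.5,
) -> TemperatureEnvelope:
    """Percentile envelope of occurrence-site temperatures.

    Temperature at a site is the value of the grid cell containing it (no
    interpolation); sites on nodata cells are ignored.  Quantiles use
    linear interpolation on the sorted sample — the index rule
    ``h = (n-1)p + 1`` — pooled across all of the species' occurrences.
    """
    if not records:
        raise ValueError("no records")
    temps = [temp_raster.sample(r.lon, r.lat) for r in records]
    temps = np.array([t for t in temps if t is not None], dtype=float)
    if temps.size == 0:
        raise ValueError("all occurrences fall on nodata temperature cells")
    lo, hi = np.quantile(temps, [q_low / 100.0, q_high / 100.0], method="linear")
    return TemperatureEnvelope(float(lo), float(hi))


# ---------------------------------------------------------------------------
# Rasterization and range assembly
# ---------------------------------------------------------------------------

def rasterize_polygon(geom: BaseGeometry, grid: RasterGrid) -> np.ndarray:
    """Boolean presence array: True where the cell centre lies in ``geom``.

    Cell-centre containment (``covers``, so boundary centres count)
    resolves presence; only cells within the polygon's bounding box are
    tested.
    """
    out = np.zeros(grid.shape, dtype=bool)
    if geom.is_empty:
        return out
    minx, miny, maxx, maxy = geom.bounds
    s = grid.cell_size
    c0 = max(0, math.floor((minx - grid.origin_x) / s - 0.5))
    c1 = min(grid.n_cols - 1, math.ceil((maxx - grid.origin_x) / s))
    r0 = max(0, math.floor((grid.origin_y - maxy) / s - 0.5))
    r1 = min(grid.n_rows - 1, math.ceil((grid.origin_y - miny) / s))
    if c1 < c0 or r1 < r0:
        return out
    xs = grid.origin_x + (np.arange(c0, c1 + 1) + 0.5) * s
    ys = grid.origin_y - (np.arange(r0, r1 + 1) + 0.5) * s
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    shapely.prepare(geom)
    inside = shapely.covers(geom, pts).reshape(gx.shape)
    out[r0:r1 + 1, c0:c1 + 1] = inside
    return out


def assign_to_biomes(
    records: Sequence[OccurrenceRecord],
    biomes: PolygonLayer,
) -> dict[int, list[OccurrenceRecord]]:
    """Group records by the index of the biome polygon covering them.

    A record on a shared biome border goes to the first covering biome in
    layer order; records in no biome are dropped with a warning.
    """
    geoms = biomes.geometries()
    for g in geoms:
        shapely.prepare(g)
    out: dict[int, list[OccurrenceRecord]] = {}
    dropped = 0
    for rec in records:
        pt = Point(rec.lon, rec.lat)
        for i, g in enumerate(geoms):
            if g.covers(pt):
                out.setdefault(i, []).append(rec)
                break
        else:
            dropped += 1
    if dropped:
        logger.warning("%d records fall in no biome polygon; dropped", dropped)
    return out


def build_range(
    records: Sequence[OccurrenceRecord],
    biomes: PolygonLayer,
    temp_raster: RasterGrid,
    grid: RasterGrid,
    config: RangeConfig | None = None,
    mask: np.ndarray | None = None,
) -> SpeciesRange:
    """Build one species' range from its (thinned) records.

    Per biome holding at least one record: convex hull of that biome's
    records, or the degenerate buffer where the hull has zero area,
    clipped to the biome polygon.  The per-biome pieces are unioned,
    rasterized by cell-centre containment, and cells whose temperature
    falls outside the species' envelope (or is nodata) are removed.
    Cells outside ``mask`` (boolean, True = study area) become nodata.
    """
    if not records:
        raise ValueError("species has zero records")
    if not grid.aligned_with(temp_raster):
        raise ValueError("analysis grid and temperature raster are not aligned")
    config = config or RangeConfig()
    species_id = records[0].species_id

    by_biome = assign_to_biomes(records, biomes)
    if not by_biome:
        raise ValueError(f"no records of {species_id} fall inside any biome")
    pieces: list[BaseGeometry] = []
    for biome_idx, recs in sorted(by_biome.items()):
        pts = [(r.lon, r.lat) for r in recs]
        hull, degenerate = convex_hull(pts)
        if degenerate:
            hull = buffer_degenerate(
                pts, config.buffer_radius_km, grid.crs_tag, config.quad_segs
            )
        if config.clip_to_biome:
            hull = hull.intersection(biomes.geometries()[biome_idx])
        if not hull.is_empty:
            pieces.append(hull)

    envelope = temperature_envelope(records, temp_raster, config.q_low, config.q_high)

    presence = np.zeros(grid.shape, dtype=bool)
    for piece in pieces:
        presence |= rasterize_polygon(piece, grid)

    temp_valid = temp_raster.valid_mask()
    tvals = temp_raster.masked()
    ok = temp_valid & (tvals >= envelope.t_low) & (tvals <= envelope.t_high)
    presence &= ok

    values = presence.astype(np.int16)
    if mask is not None:
        values[~mask] = RANGE_NODATA
    raster = grid.copy_with(values, nodata=RANGE_NODATA)
    return SpeciesRange(
        species_id=species_id, polygons=pieces, envelope=envelope, raster=raster
    )
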