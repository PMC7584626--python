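"""Derived predictor rasters and the aligned predictor stack.

The driver analysis uses seven predictors: two contemporary climate
layers (annual mean temperature, annual precipitation), topographic
heterogeneity, NDVI, two historical climate-change velocities
(temperature and precipitation, Last Glacial Maximum to present) and
mountain-uplift age.  This module computes the derived ones.

Climate-change velocity is the temporal rate of change divided by the
local spatial gradient of the same variable: with only two climate
states available (present and LGM, 21 000 years apart) the temporal rate
is the absolute anomaly over that interval, and the spatial gradient is
taken on the current climate surface with a 3x3 Horn kernel.  Cells with
a near-zero spatial gradient would yield unbounded velocities; the
gradient is floored at a small configurable value instead so velocity
stays finite over flat terrain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geodata import AlignmentError, PolygonLayer, RasterGrid, require_aligned
from .ranges import rasterize_polygon

logger = logging.getLogger("rangestack")

#: the seven predictor names, fixed
PREDICTOR_NAMES = (
    "temperature",
    "precipitation",
    "topo_heterogeneity",
    "ndvi",
    "temperature_velocity",
    "precipitation_velocity",
    "uplift_age",
)

#: km per degree of latitude, used when grids are georeferenced in degrees
KM_PER_DEGREE = 111.32


@dataclass
class VelocityParams:
    """Climate-change velocity parameters.

    years_elapsed : time between the two climate states (yr); 21 000 for
        LGM to present.
    gradient_floor : minimum spatial gradient (climate units per km)
        substituted where the surface is flatter, keeping velocity finite.
    kernel : "horn" (3x3 third-order finite difference) or "central".
    gradient_surface : which climate state carries the spatial gradient.
    """

    years_elapsed: float = 21000.0
    gradient_floor: float = 1e-6
    kernel: str = "horn"
    gradient_surface: str = "current"  # "current" | "past" | "mean"

    def __post_init__(self) -> None:
        if self.years_elapsed <= 0:
            raise ValueError("years_elapsed must be positive")
        if self.gradient_floor <= 0:
            raise ValueError("gradient_floor must be positive")
        if self.kernel not in ("horn", "central"):
            raise ValueError(f"unknown gradient kernel {self.kernel!r}")


def cell_size_km(grid: RasterGrid) -> float:
    """Cell edge length in km, honouring the grid's CRS tag."""
    if grid.crs_tag == "wgs84":
        return grid.cell_size * KM_PER_DEGREE
    return grid.cell_size


# ---------------------------------------------------------------------------
# Spatial gradient
# ---------------------------------------------------------------------------

def spatial_gradient(
    raster: RasterGrid,
    cell_km: float | None = None,
    kernel: str = "horn",
) -> RasterGrid:
    """Gradient magnitude of a climate surface, in value units per km.

    Interior cells use the Horn 3x3 third-order finite-difference kernel
    (the standard GIS slope operator); the border ring falls back to
    one-sided/central differences.  Nodata propagates: any nodata cell in
    a cell's neighbourhood makes that cell nodata.
    """
    if raster.n_rows < 3 or raster.n_cols < 3:
        raise ValueError("gradient needs at least a 3x3 grid")
    s = cell_km if cell_km is not None else cell_size_km(raster)
    z = raster.masked()

    gy_c, gx_c = np.gradient(z, s)  # central in interior, one-sided at edges
    if kernel == "central":
        mag = np.hypot(gx_c, gy_c)
    elif kernel == "horn":
        mag = np.hypot(gx_c, gy_c)  # border ring keeps one-sided differences
        gx = (
            (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
            - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
        ) / (8.0 * s)
        gy = (
            (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
            - (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
        ) / (8.0 * s)
        mag[1:-1, 1:-1] = np.hypot(gx, gy)
    else:
        raise ValueError(f"unknown gradient kernel {kernel!r}")

    mag[np.isnan(z)] = np.nan  # the kernel omits the centre cell
    out = np.where(np.isnan(mag), raster.nodata, mag)
    return raster.copy_with(out)


# ---------------------------------------------------------------------------
# Climate-change velocity
# ---------------------------------------------------------------------------

def climate_velocity(
    current: RasterGrid,
    past: RasterGrid,
    params: VelocityParams | None = None,
) -> RasterGrid:
    """|current − past| / years, divided by the floored spatial gradient.

    Units are km/yr.  Nodata wherever either input is nodata (or the
    gradient neighbourhood touches nodata).
    """
    params = params or VelocityParams()
    if not current.aligned_with(past):
        raise AlignmentError("current and past climate rasters are not aligned")
    surface = {
        "current": lambda: current,
        "past": lambda: past,
        "mean": lambda: current.copy_with(
            (current.masked() + past.masked()) / 2.0
        ),
    }[params.gradient_surface]()
    grad = spatial_gradient(surface, kernel=params.kernel).masked()
    grad = np.maximum(grad, params.gradient_floor)
    rate = np.abs(current.masked() - past.masked()) / params.years_elapsed
    vel = rate / grad
    out = np.where(np.isnan(vel), current.nodata, vel)
    return current.copy_with(out)


def average_rasters(grids: Sequence[RasterGrid]) -> RasterGrid:
    """Cell-wise arithmetic mean; nodata where any input is nodata.

    Used to combine paleoclimate simulations from multiple general
    circulation models into one LGM layer.
    """
    if not grids:
        raise ValueError("no rasters to average")
    require_aligned({f"raster[{i}]": g for i, g in enumerate(grids)})
    stack = np.stack([g.masked() for g in grids])
    mean = stack.mean(axis=0)  # NaN if any layer NaN
    out = np.where(np.isnan(mean), grids[0].nodata, mean)
    return grids[0].copy_with(out)


# ---------------------------------------------------------------------------
# Topographic heterogeneity
# ---------------------------------------------------------------------------

def topo_heterogeneity(fine_dem: RasterGrid, coarse_grid: RasterGrid) -> RasterGrid:
    """Sample SD of fine-resolution elevation within each coarse cell.

    The fine cell size must divide the coarse cell size by an integer
    factor f, and the grids must be co-registered (same origin, fine
    shape = coarse shape x f).  Each coarse value is the sample standard
    deviation (denominator n-1) of the f^2 fine cells it covers; blocks
    with fine nodata use the remaining cells, and blocks with fewer than
    two valid cells are nodata.
    """
    ratio = coarse_grid.cell_size / fine_dem.cell_size
    f = int(round(ratio))
    if f < 1 or abs(ratio - f) > 1e-9:
        raise ValueError(
            f"fine cell size must divide coarse cell size; ratio {ratio:g}"
        )
    expected = (coarse_grid.n_rows * f, coarse_grid.n_cols * f)
    if fine_dem.shape != expected:
        raise ValueError(
            f"fine DEM shape {fine_dem.shape} does not cover the coarse grid "
            f"(expected {expected})"
        )
    if not (
        np.isclose(fine_dem.origin_x, coarse_grid.origin_x)
        and np.isclose(fine_dem.origin_y, coarse_grid.origin_y)
    ):
        raise ValueError("fine DEM and coarse grid are not co-registered")

    z = fine_dem.masked()
    blocks = z.reshape(coarse_grid.n_rows, f, coarse_grid.n_cols, f)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(
        coarse_grid.n_rows, coarse_grid.n_cols, f * f
    )
    n_valid = np.sum(~np.isnan(blocks), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(blocks, axis=2, ddof=1)
    out = np.where(n_valid >= 2, sd, coarse_grid.nodata)
    return coarse_grid.copy_with(out)


# ---------------------------------------------------------------------------
# Mountain-uplift age raster
# ---------------------------------------------------------------------------

def rasterize_uplift(mountains: PolygonLayer, grid: RasterGrid) -> RasterGrid:
    """Paint each cell with the uplift age (Myr) of the range covering it.

    Cells in no mountain polygon get 0 (unuplifted lowland); where ranges
    overlap the older age wins.
    """
    ages = mountains.attribute("uplift_age_myr")
    if any(a < 0 for a in ages):
        raise ValueError("uplift ages must be non-negative")
    out = np.zeros(grid.shape, dtype=float)
    order = np.argsort(ages)  # paint oldest last so it wins overlaps
    for i in order:
        geom = mountains.geometries()[i]
        covered = rasterize_polygon(geom, grid)
        out[covered] = ages[i]
    return grid.copy_with(out, nodata=-9999.0)


# ---------------------------------------------------------------------------
# Stack assembly
# ---------------------------------------------------------------------------

@dataclass
class PredictorStack:
    """The seven named, grid-aligned predictor rasters."""

    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        missing = set(PREDICTOR_NAMES) - set(self.layers)
        extra = set(self.layers) - set(PREDICTOR_NAMES)
        if missing or extra:
            raise ValueError(
                f"predictor stack needs exactly {PREDICTOR_NAMES}; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )
        require_aligned(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return self.layers[PREDICTOR_NAMES[0]]

    def validity_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.valid_mask()
        return mask

    def to_matrix(self, cells: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, 7) matrix of predictor values at the given boolean mask."""
        mask = self.validity_mask() if cells is None else cells
        return np.column_stack(
            [self.layers[name].values[mask] for name in PREDICTOR_NAMES]
        )


def assemble_stack(layers: Mapping[str, RasterGrid]) -> PredictorStack:
    """Validate names and alignment and wrap the layers in a stack."""
    return PredictorStack(layers=dict(layers))
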