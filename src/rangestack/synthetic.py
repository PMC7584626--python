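"""Synthetic study system with full ground truth.

Generates, from one master seed, a desk-scale analogue of an arid
mountainous study region: smooth spatially autocorrelated climate fields
with a colder/drier Last Glacial Maximum state, a fine-resolution DEM, a
Voronoi biome mosaic partitioning an elliptical study area, mountain
polygons carrying uplift ages, a pool of species with known thermal
niches and biome memberships, clustered occurrence samples with
diurnal/nocturnal labels, and richness-like counts drawn from a known
log-linear model.  Every downstream stage of the pipeline can therefore
be checked against a known truth.

Defaults mirror the study system the pipeline is modelled on: 171
species of which a fraction 101/171 is diurnal and 62/171 endemic, a
species-level mean of about 50 raw occurrence records, six biomes, and a
1-km analysis grid with a 10x finer DEM.  Smooth fields are low-order
cosine mixtures, so the generator is reproducible from the seed alone.

The master seed is split into named sub-seeds (landscape, species,
counts) so each stage can be regenerated independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .geodata import OccurrenceRecord, PolygonLayer, RasterGrid
from .ranges import rasterize_polygon

logger = logging.getLogger("rangestack")

NODATA = -9999.0


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study system."""

    seed: int = 0
    # grid: centred on the origin so local-km coordinates stay inside the
    # numeric bounds of geographic records
    n_rows: int = 120
    n_cols: int = 100
    cell_size_km: float = 1.0
    fine_factor: int = 10  # DEM resolution = cell_size / fine_factor

    # climate fields
    base_temp_c: float = 18.0
    lat_gradient_c_per_km: float = -0.05
    elev_lapse_c_per_m: float = -0.0065
    temp_noise_c: float = 1.0
    lgm_cooling_mean_c: float = 5.0
    lgm_cooling_amp_c: float = 2.0
    base_precip_mm: float = 300.0
    precip_per_m: float = 0.05
    precip_x_gradient_mm_per_km: float = 2.0
    precip_noise_mm: float = 120.0
    ndvi_noise: float = 0.2
    lgm_drying_mean_mm: float = 60.0
    lgm_drying_amp_mm: float = 30.0

    # terrain
    n_peaks: int = 5
    peak_height_m: tuple[float, float] = (1200.0, 3000.0)
    peak_sigma_km: tuple[float, float] = (10.0, 25.0)

    # regions
    n_biomes: int = 6
    n_mountains: int = 3
    uplift_age_range_myr: tuple[float, float] = (3.0, 20.0)

    # species pool
    n_species: int = 171
    p_diurnal: float = 101.0 / 171.0
    p_endemic: float = 62.0 / 171.0
    niche_width_c: tuple[float, float] = (2.0, 8.0)
    occ_mean: float = 50.0
    min_occurrences: int = 2
    max_biomes_per_species: int = 3
    max_clusters: int = 4
    cluster_sd_km: float = 6.0
    jitter_frac: float = 0.0  # 0 = occurrences at cell centres

    # ground-truth log-linear model: intercept + one coefficient per
    # predictor (temperature, precipitation, topo_heterogeneity, ndvi,
    # temperature_velocity, precipitation_velocity, uplift_age), on
    # z-scored predictors
    glm_truth: tuple[float, ...] = (2.0, 0.6, -0.2, 0.15, -0.15, 0.25, 0.05, 0.1)

    def __post_init__(self) -> None:
        if self.n_rows < 20 or self.n_cols < 20:
            raise ValueError("synthetic grid must be at least 20x20")
        if not 0.0 <= self.p_diurnal <= 1.0:
            raise ValueError("p_diurnal must be in [0, 1]")
        if self.n_species < 1 or self.n_biomes < 1:
            raise ValueError("counts must be positive")

    def sub_seeds(self) -> dict[str, np.random.SeedSequence]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return dict(zip(("landscape", "species", "counts"), children))


@dataclass
class Landscape:
    """The raster/vector inputs of one synthetic run."""

    grid: RasterGrid  # template (values unused)
    temperature: RasterGrid
    precipitation: RasterGrid
    ndvi: RasterGrid
    lgm_temperature: RasterGrid
    lgm_precipitation: RasterGrid
    dem: RasterGrid  # coarse (block-mean of fine)
    fine_dem: RasterGrid
    biomes: PolygonLayer
    mountains: PolygonLayer
    mask_polygon: PolygonLayer
    mask: np.ndarray  # boolean study-area cells


@dataclass
class TrueRange:
    """Ground truth for one synthetic species."""

    species_id: str
    cells: np.ndarray  # boolean array on the analysis grid
    t_low: float
    t_high: float
    biome_ids: tuple[int, ...]
    activity: str
    endemic: bool


def _smooth_field(
    rng: np.random.Generator,
    xs: np.ndarray,
    ys: np.ndarray,
    n_modes: int = 6,
    wavelength_km: tuple[float, float] = (25.0, 80.0),
) -> np.ndarray:
    """Low-order cosine mixture: smooth, roughly unit-amplitude, zero-mean."""
    out = np.zeros_like(xs, dtype=float)
    for _ in range(n_modes):
        wl = rng.uniform(*wavelength_km)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        kx, ky = math.cos(theta) / wl, math.sin(theta) / wl
        amp = rng.uniform(0.5, 1.0)
        out += amp * np.cos(2.0 * math.pi * (kx * xs + ky * ys) + phase)
    return out / (0.75 * n_modes)


def _grid_template(scenario: SyntheticScenario) -> RasterGrid:
    s = scenario.cell_size_km
    return RasterGrid(
        values=np.zeros((scenario.n_rows, scenario.n_cols)),
        origin_x=-scenario.n_cols * s / 2.0,
        origin_y=scenario.n_rows * s / 2.0,
        cell_size=s,
        nodata=NODATA,
        crs_tag="local-km",
    )


def make_landscape(scenario: SyntheticScenario, seed=None) -> Landscape:
    """Build the raster and vector inputs of a synthetic study system."""
    rng = np.random.default_rng(
        seed if seed is not None else scenario.sub_seeds()["landscape"]
    )
    grid = _grid_template(scenario)
    half_w = scenario.n_cols * scenario.cell_size_km / 2.0
    half_h = scenario.n_rows * scenario.cell_size_km / 2.0
    if half_w > 180.0 or half_h > 90.0:
        raise ValueError("local-km grid exceeds record coordinate bounds")

    # fine DEM: Gaussian peaks + smooth noise
    f = scenario.fine_factor
    fine_cell = scenario.cell_size_km / f
    fx = grid.origin_x + (np.arange(scenario.n_cols * f) + 0.5) * fine_cell
    fy = grid.origin_y - (np.arange(scenario.n_rows * f) + 0.5) * fine_cell
    fgx, fgy = np.meshgrid(fx, fy)
    dem_fine = np.zeros_like(fgx)
    for _ in range(scenario.n_peaks):
        cx = rng.uniform(-half_w * 0.8, half_w * 0.8)
        cy = rng.uniform(-half_h * 0.8, half_h * 0.8)
        h = rng.uniform(*scenario.peak_height_m)
        sig = rng.uniform(*scenario.peak_sigma_km)
        dem_fine += h * np.exp(-((fgx - cx) ** 2 + (fgy - cy) ** 2) / (2 * sig**2))
    dem_fine += 120.0 * _smooth_field(rng, fgx, fgy)
    dem_fine = np.clip(dem_fine, 0.0, None)
    fine_dem = RasterGrid(
        dem_fine, grid.origin_x, grid.origin_y, fine_cell, NODATA, grid.crs_tag
    )
    dem_coarse = dem_fine.reshape(scenario.n_rows, f, scenario.n_cols, f).mean(
        axis=(1, 3)
    )

    # study-area mask: inscribed ellipse
    ellipse = affinity.scale(
        Point(0.0, 0.0).buffer(1.0, quad_segs=64), half_w * 0.92, half_h * 0.92
    )
    mask_layer = PolygonLayer([(ellipse, {"name": "study-area"})])
    mask = rasterize_polygon(ellipse, grid)

    # climate surfaces on the coarse grid
    cgx, cgy = grid.cell_centers()
    temp = (
        scenario.base_temp_c
        + scenario.lat_gradient_c_per_km * cgy
        + scenario.elev_lapse_c_per_m * dem_coarse
        + scenario.temp_noise_c * _smooth_field(rng, cgx, cgy)
    )
    cooling = np.clip(
        scenario.lgm_cooling_mean_c
        + scenario.lgm_cooling_amp_c * _smooth_field(rng, cgx, cgy),
        0.5,
        None,
    )
    precip = np.clip(
        scenario.base_precip_mm
        + scenario.precip_per_m * dem_coarse
        + scenario.precip_x_gradient_mm_per_km * cgx
        + scenario.precip_noise_mm * _smooth_field(rng, cgx, cgy),
        30.0,
        None,
    )
    drying = np.clip(
        scenario.lgm_drying_mean_mm
        + scenario.lgm_drying_amp_mm * _smooth_field(rng, cgx, cgy),
        0.0,
        None,
    )
    ndvi = np.clip(
        precip / (precip + 400.0)
        + scenario.ndvi_noise * _smooth_field(rng, cgx, cgy),
        0.0,
        1.0,
    )

    def _masked_grid(vals: np.ndarray) -> RasterGrid:
        out = vals.astype(float, copy=True)
        out[~mask] = NODATA
        return grid.copy_with(out)

    # biome mosaic: Voronoi cells of random seed points, clipped to the mask
    seeds = []
    while len(seeds) < scenario.n_biomes:
        p = Point(rng.uniform(-half_w, half_w), rng.uniform(-half_h, half_h))
        if ellipse.contains(p):
            seeds.append(p)
    cells = voronoi_diagram(
        MultiPoint(seeds), envelope=box(-half_w, -half_h, half_w, half_h)
    )
    biome_feats: list[tuple] = [None] * scenario.n_biomes
    for cell in cells.geoms:
        for i, p in enumerate(seeds):
            if cell.covers(p):
                biome_feats[i] = (cell.intersection(ellipse), {"biome_id": i})
                break
    biomes = PolygonLayer([ft for ft in biome_feats if ft is not None])

    # mountain ranges: random ellipses with uplift ages
    mountain_feats = []
    for i in range(scenario.n_mountains):
        cx = rng.uniform(-half_w * 0.7, half_w * 0.7)
        cy = rng.uniform(-half_h * 0.7, half_h * 0.7)
        rx = rng.uniform(0.15 * half_w, 0.35 * half_w)
        ry = rng.uniform(0.15 * half_h, 0.35 * half_h)
        angle = rng.uniform(0.0, 180.0)
        geom = affinity.rotate(
            affinity.scale(Point(cx, cy).buffer(1.0, quad_segs=32), rx, ry), angle
        )
        age = float(rng.uniform(*scenario.uplift_age_range_myr))
        mountain_feats.append((geom, {"uplift_age_myr": age, "name": f"range-{i}"}))
    mountains = PolygonLayer(mountain_feats)

    return Landscape(
        grid=grid,
        temperature=_masked_grid(temp),
        precipitation=_masked_grid(precip),
        ndvi=_masked_grid(ndvi),
        lgm_temperature=_masked_grid(temp - cooling),
        lgm_precipitation=_masked_grid(np.clip(precip - drying, 5.0, None)),
        dem=grid.copy_with(dem_coarse),
        fine_dem=fine_dem,
        biomes=biomes,
        mountains=mountains,
        mask_polygon=mask_layer,
        mask=mask,
    )


def biome_id_raster(landscape: Landscape) -> np.ndarray:
    """Integer biome id per cell (-1 where no biome covers the centre)."""
    out = np.full(landscape.grid.shape, -1, dtype=int)
    for geom, attrs in landscape.biomes.features:
        out[rasterize_polygon(geom, landscape.grid)] = attrs["biome_id"]
    return out


def make_species_pool(
    scenario: SyntheticScenario,
    landscape: Landscape,
    seed=None,
) -> tuple[list[TrueRange], list[OccurrenceRecord]]:
    """Draw species with thermal niches and clustered occurrence samples.

    Each species occupies a random subset of biomes and, within them, the
    cells whose temperature falls inside its niche interval; occurrences
    are sampled from those cells around a few cluster centres, so samples
    are spatially aggregated the way field records are.  Every occurrence
    lies inside its species' true range by construction.  A species whose
    drawn niche yields an empty range gets its niche resampled (logged).
    """
    rng = np.random.default_rng(
        seed if seed is not None else scenario.sub_seeds()["species"]
    )
    grid = landscape.grid
    biome_ids = biome_id_raster(landscape)
    temp = landscape.temperature.masked()
    usable = landscape.mask & (biome_ids >= 0) & ~np.isnan(temp)

    rows_all, cols_all = np.where(usable)
    true_ranges: list[TrueRange] = []
    records: list[OccurrenceRecord] = []
    n_resampled = 0
    for sp_idx in range(scenario.n_species):
        sp = f"sp{sp_idx:03d}"
        for attempt in range(100):
            k = rng.integers(1, scenario.max_biomes_per_species + 1)
            k = min(k, len(landscape.biomes))
            subset = tuple(
                sorted(rng.choice(len(landscape.biomes), size=k, replace=False))
            )
            in_biomes = usable & np.isin(biome_ids, subset)
            cand_r, cand_c = np.where(in_biomes)
            if cand_r.size == 0:
                continue
            centre_i = rng.integers(cand_r.size)
            t_centre = temp[cand_r[centre_i], cand_c[centre_i]]
            width = rng.uniform(*scenario.niche_width_c)
            t_low, t_high = t_centre - width / 2.0, t_centre + width / 2.0
            cells = in_biomes & (temp >= t_low) & (temp <= t_high)
            if cells.any():
                break
            n_resampled += 1
        else:
            raise RuntimeError(f"could not draw a non-empty range for {sp}")

        rr, cc = np.where(cells)
        n_occ = max(scenario.min_occurrences, int(rng.poisson(scenario.occ_mean)))
        n_clusters = int(rng.integers(1, scenario.max_clusters + 1))
        centres = rng.integers(rr.size, size=n_clusters)
        split = rng.multinomial(n_occ, np.full(n_clusters, 1.0 / n_clusters))
        chosen: list[int] = []
        for centre, m in zip(centres, split):
            if m == 0:
                continue
            d2 = (rr - rr[centre]) ** 2 + (cc - cc[centre]) ** 2
            w = np.exp(-d2 * grid.cell_size**2 / (2.0 * scenario.cluster_sd_km**2))
            w /= w.sum()
            chosen.extend(rng.choice(rr.size, size=m, p=w))

        activity = "diurnal" if rng.random() < scenario.p_diurnal else "nocturnal"
        endemic = bool(rng.random() < scenario.p_endemic)
        for idx in chosen:
            x, y = grid.cell_center(rr[idx], cc[idx])
            if scenario.jitter_frac > 0:
                x += rng.uniform(-0.5, 0.5) * scenario.jitter_frac * grid.cell_size
                y += rng.uniform(-0.5, 0.5) * scenario.jitter_frac * grid.cell_size
            records.append(
                OccurrenceRecord(
                    species_id=sp, lon=float(x), lat=float(y),
                    activity=activity, endemic=endemic, source="synthetic",
                )
            )
        true_ranges.append(
            TrueRange(
                species_id=sp, cells=cells, t_low=float(t_low),
                t_high=float(t_high), biome_ids=subset,
                activity=activity, endemic=endemic,
            )
        )
    if n_resampled:
        logger.info("resampled %d empty niches while drawing species", n_resampled)
    logger.info(
        "species pool: %d species, %d occurrence records",
        len(true_ranges), len(records),
    )
    return true_ranges, records


def make_glm_counts(stack, beta: Sequence[float], seed=None) -> RasterGrid:
    """Poisson counts from a known log-linear model on the stack.

    ``beta`` is the intercept followed by one coefficient per predictor,
    applied to z-scored predictor values over the stack's validity mask.
    Standardized values are winsorized at +/-5: climate-change velocity is
    heavy-tailed (a handful of near-flat-gradient cells reach z > 50), and
    without the cap a nonzero velocity slope would put astronomically
    large counts on those few cells instead of richness-like values.
    Cells outside the mask are nodata.
    """
    from .drivers import zscore_columns  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    mask = stack.validity_mask()
    X = np.clip(zscore_columns(stack.to_matrix(mask)), -5.0, 5.0)
    if beta.size != X.shape[1] + 1:
        raise ValueError(
            f"beta length {beta.size} != 1 + {X.shape[1]} predictors"
        )
    eta = beta[0] + X @ beta[1:]
    if np.max(np.abs(eta)) > 50.0:
        raise ValueError(
            "linear predictor exceeds 50; choose smaller coefficients"
        )
    counts = np.full(stack.grid.shape, -1, dtype=np.int64)
    counts[mask] = rng.poisson(np.exp(eta))
    return stack.grid.copy_with(counts, nodata=-1)
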