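import numpy as np
import pytest
from shapely.geometry import box

from rangestack import (
    AlignmentError,
    PolygonLayer,
    RasterGrid,
    VelocityParams,
    assemble_stack,
    average_rasters,
    climate_velocity,
    rasterize_uplift,
    spatial_gradient,
    topo_heterogeneity,
)
from rangestack.predictors import PREDICTOR_NAMES


def km_grid(values, cell=1.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, 0.0, values.shape[0] * cell, cell)


def plane(n_rows=20, n_cols=30, a=10.0, bx=0.0, by=0.0, cell=1.0):
    """T = a + bx*x + by*y evaluated at cell centres."""
    g = km_grid(np.zeros((n_rows, n_cols)), cell)
    xs, ys = g.cell_centers()
    return g.copy_with(a + bx * xs + by * ys)


# ---------------------------------------------------------------------------
# spatial gradient
# ---------------------------------------------------------------------------

def test_constant_field_has_zero_gradient():
    g = spatial_gradient(km_grid(np.full((10, 10), 3.0)))
    assert np.allclose(g.values, 0.0)


def test_plane_gradient_is_the_slope_in_the_interior():
    g = spatial_gradient(plane(bx=0.01))
    interior = g.values[1:-1, 1:-1]
    assert np.max(np.abs(interior - 0.01)) <= 1e-9 * 0.01


def test_gradient_magnitude_is_isotropic():
    gx = spatial_gradient(plane(bx=0.01)).values[1:-1, 1:-1]
    gy = spatial_gradient(plane(by=0.01)).values[1:-1, 1:-1]
    assert np.allclose(gx, gy)


def test_small_grid_rejected():
    with pytest.raises(ValueError):
        spatial_gradient(km_grid(np.zeros((2, 5))))


def test_gradient_nodata_propagates_to_neighbourhood():
    vals = np.full((9, 9), 1.0)
    vals[4, 4] = -9999.0
    g = spatial_gradient(km_grid(vals))
    assert not g.valid_mask()[4, 4]
    assert not g.valid_mask()[3, 4]  # neighbour touched by the kernel
    assert g.valid_mask()[0, 0]


# ---------------------------------------------------------------------------
# climate velocity
# ---------------------------------------------------------------------------

def test_no_change_means_zero_velocity():
    cur = plane(bx=0.02)
    vel = climate_velocity(cur, cur)
    assert np.allclose(vel.values, 0.0)


def test_velocity_closed_form_on_a_plane():
    cur = plane(bx=0.01)
    past = cur.copy_with(cur.values - 4.2)
    vel = climate_velocity(cur, past, VelocityParams(years_elapsed=21000.0))
    expected = (4.2 / 21000.0) / 0.01  # 0.02 km/yr
    interior = vel.values[1:-1, 1:-1]
    assert np.max(np.abs(interior - expected)) <= 1e-9 * expected


def test_flat_field_engages_the_gradient_floor():
    cur = km_grid(np.full((10, 10), 15.0))
    past = cur.copy_with(cur.values - 2.0)
    params = VelocityParams(gradient_floor=1e-6)
    vel = climate_velocity(cur, past, params)
    expected = 2.0 / (21000.0 * 1e-6)
    assert np.allclose(vel.values, expected)
    assert np.isfinite(vel.values).all()


def test_velocity_scales_with_anomaly_and_inverse_gradient():
    cur = plane(bx=0.01)
    v1 = climate_velocity(cur, cur.copy_with(cur.values - 1.0)).values[5, 5]
    v2 = climate_velocity(cur, cur.copy_with(cur.values - 2.0)).values[5, 5]
    assert v2 == pytest.approx(2 * v1)
    steep = plane(bx=0.02)
    v3 = climate_velocity(steep, steep.copy_with(steep.values - 1.0)).values[5, 5]
    assert v3 == pytest.approx(v1 / 2)


def test_misaligned_inputs_rejected():
    with pytest.raises(AlignmentError):
        climate_velocity(plane(), plane(n_cols=31))


def test_velocity_nonnegative_everywhere():
    rng = np.random.default_rng(0)
    cur = km_grid(rng.normal(15, 3, (15, 15)))
    past = km_grid(rng.normal(10, 3, (15, 15)))
    vel = climate_velocity(cur, past)
    assert (vel.values[vel.valid_mask()] >= 0).all()


# ---------------------------------------------------------------------------
# raster averaging
# ---------------------------------------------------------------------------

def test_average_of_identical_grids_is_identity():
    g = plane(bx=0.3)
    assert np.allclose(average_rasters([g, g]).values, g.values)


def test_average_of_zero_and_two_is_one():
    z = km_grid(np.zeros((4, 4)))
    two = z.copy_with(np.full((4, 4), 2.0))
    assert np.allclose(average_rasters([z, two]).values, 1.0)


def test_average_matches_per_cell_oracle_and_propagates_nodata():
    rng = np.random.default_rng(1)
    a_vals, b_vals = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
    a_vals[2, 2] = -9999.0
    a, b = km_grid(a_vals), km_grid(b_vals)
    out = average_rasters([a, b])
    for r in range(5):
        for c in range(6):
            if (r, c) == (2, 2):
                assert out.values[r, c] == out.nodata
            else:
                assert out.values[r, c] == pytest.approx(
                    (a_vals[r, c] + b_vals[r, c]) / 2
                )


# ---------------------------------------------------------------------------
# topographic heterogeneity
# ---------------------------------------------------------------------------

def fine_and_coarse(fine_vals, f):
    fine_vals = np.asarray(fine_vals, dtype=float)
    nr, nc = fine_vals.shape[0] // f, fine_vals.shape[1] // f
    coarse = RasterGrid(np.zeros((nr, nc)), 0.0, float(nr), 1.0)
    fine = RasterGrid(fine_vals, 0.0, float(nr), 1.0 / f)
    return fine, coarse


def test_flat_dem_has_zero_heterogeneity():
    fine, coarse = fine_and_coarse(np.full((40, 40), 500.0), 10)
    out = topo_heterogeneity(fine, coarse)
    assert np.allclose(out.values, 0.0)


def test_checkerboard_block_sample_sd():
    # one coarse cell covering 100 fine cells, 50 zeros and 50 ones:
    # sample SD = sqrt(25/99)
    vals = np.indices((10, 10)).sum(axis=0) % 2
    fine, coarse = fine_and_coarse(vals.astype(float), 10)
    out = topo_heterogeneity(fine, coarse)
    assert out.values[0, 0] == pytest.approx(np.sqrt(25.0 / 99.0), abs=1e-12)


def test_random_dem_matches_blockwise_oracle():
    rng = np.random.default_rng(8)
    f = 5
    vals = rng.normal(1000, 200, size=(20, 30))
    fine, coarse = fine_and_coarse(vals, f)
    out = topo_heterogeneity(fine, coarse)
    for r in range(out.n_rows):
        for c in range(out.n_cols):
            block = vals[r * f:(r + 1) * f, c * f:(c + 1) * f]
            assert out.values[r, c] == pytest.approx(block.std(ddof=1))


def test_shift_invariance_and_linear_scaling():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=(20, 20))
    fine, coarse = fine_and_coarse(vals, 4)
    base = topo_heterogeneity(fine, coarse).values
    shifted = topo_heterogeneity(fine.copy_with(vals + 1234.5), coarse).values
    scaled = topo_heterogeneity(fine.copy_with(vals * 3.0), coarse).values
    assert np.allclose(shifted, base)
    assert np.allclose(scaled, 3.0 * base)


def test_non_integer_factor_rejected():
    fine = RasterGrid(np.zeros((30, 30)), 0.0, 10.0, 1.0 / 3.0)
    coarse = RasterGrid(np.zeros((10, 10)), 0.0, 10.0, 0.5)
    with pytest.raises(ValueError, match="divide"):
        topo_heterogeneity(fine, coarse)


def test_blocks_with_too_few_valid_cells_are_nodata():
    vals = np.full((4, 4), 100.0)
    vals[0:2, 0:2] = -9999.0
    vals[0, 2] = -9999.0  # 3 valid cells remain in block (0,1)
    fine = RasterGrid(vals, 0.0, 2.0, 0.5, nodata=-9999.0)
    coarse = RasterGrid(np.zeros((2, 2)), 0.0, 2.0, 1.0)
    out = topo_heterogeneity(fine, coarse)
    assert out.values[0, 0] == out.nodata  # 0 valid
    assert out.values[0, 1] == pytest.approx(0.0)  # 3 valid, all equal
    assert out.values[1, 1] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# uplift-age raster
# ---------------------------------------------------------------------------

def test_uplift_ages_paint_covered_cells():
    grid = RasterGrid(np.zeros((10, 10)), 0.0, 10.0, 1.0)
    layer = PolygonLayer([(box(0, 0, 5, 10), {"uplift_age_myr": 19.0})])
    out = rasterize_uplift(layer, grid)
    assert (out.values[:, :5] == 19.0).all()
    assert (out.values[:, 5:] == 0.0).all()


def test_overlapping_ranges_keep_the_older_age():
    grid = RasterGrid(np.zeros((10, 10)), 0.0, 10.0, 1.0)
    layer = PolygonLayer(
        [(box(2, 2, 8, 8), {"uplift_age_myr": 5.0}),
         (box(4, 4, 6, 6), {"uplift_age_myr": 19.0})]
    )
    out = rasterize_uplift(layer, grid)
    assert out.values[5, 5] == 19.0
    assert out.values[3, 3] == 5.0


def test_negative_age_rejected():
    grid = RasterGrid(np.zeros((5, 5)), 0.0, 5.0, 1.0)
    layer = PolygonLayer([(box(0, 0, 2, 2), {"uplift_age_myr": -1.0})])
    with pytest.raises(ValueError):
        rasterize_uplift(layer, grid)


def test_uplift_matches_point_in_polygon_oracle():
    rng = np.random.default_rng(12)
    grid = RasterGrid(np.zeros((20, 20)), 0.0, 20.0, 1.0)
    layer = PolygonLayer(
        [(box(1, 1, 12, 9), {"uplift_age_myr": 7.0}),
         (box(8, 5, 19, 18), {"uplift_age_myr": 15.0})]
    )
    out = rasterize_uplift(layer, grid)
    from shapely.geometry import Point

    for _ in range(500):
        r = int(rng.integers(0, 20))
        c = int(rng.integers(0, 20))
        x, y = grid.cell_center(r, c)
        expected = 0.0
        for geom, attrs in layer.features:
            if geom.covers(Point(x, y)):
                expected = max(expected, attrs["uplift_age_myr"])
        assert out.values[r, c] == expected


# ---------------------------------------------------------------------------
# stack assembly
# ---------------------------------------------------------------------------

def seven_layers():
    rng = np.random.default_rng(3)
    return {name: km_grid(rng.normal(size=(6, 6))) for name in PREDICTOR_NAMES}


def test_seven_aligned_layers_assemble():
    stack = assemble_stack(seven_layers())
    assert set(stack.layers) == set(PREDICTOR_NAMES)


def test_missing_layer_name_rejected():
    layers = seven_layers()
    del layers["ndvi"]
    with pytest.raises(ValueError, match="ndvi"):
        assemble_stack(layers)


def test_extra_layer_name_rejected():
    layers = seven_layers()
    layers["slope"] = layers["temperature"]
    with pytest.raises(ValueError, match="slope"):
        assemble_stack(layers)


def test_misaligned_layer_rejected():
    layers = seven_layers()
    layers["ndvi"] = RasterGrid(np.zeros((6, 6)), 0.25, 6.0, 1.0)
    with pytest.raises(AlignmentError):
        assemble_stack(layers)


def test_validity_mask_is_the_intersection_of_layer_masks():
    layers = seven_layers()
    a = layers["temperature"].values.copy()
    a[0, 0] = -9999.0
    layers["temperature"] = layers["temperature"].copy_with(a)
    b = layers["uplift_age"].values.copy()
    b[3, 3] = -9999.0
    layers["uplift_age"] = layers["uplift_age"].copy_with(b)
    stack = assemble_stack(layers)
    expected = np.ones((6, 6), dtype=bool)
    expected[0, 0] = expected[3, 3] = False
    assert np.array_equal(stack.validity_mask(), expected)
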