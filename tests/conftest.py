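import numpy as np
import pytest

from rangestack import (
    RasterGrid,
    SyntheticScenario,
    make_landscape,
    make_species_pool,
)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A reduced study system: fast enough for per-test use, big enough
    for every pipeline stage to be non-trivial."""
    return SyntheticScenario(
        seed=11, n_species=30, n_rows=60, n_cols=50, fine_factor=5, occ_mean=40.0
    )


@pytest.fixture(scope="session")
def small_landscape(small_scenario):
    return make_landscape(small_scenario)


@pytest.fixture(scope="session")
def small_pool(small_scenario, small_landscape):
    return make_species_pool(small_scenario, small_landscape)


@pytest.fixture()
def flat_grid() -> RasterGrid:
    """10x12 all-zero grid, 1-km cells, top-left corner at (0, 10)."""
    return RasterGrid(
        values=np.zeros((10, 12)), origin_x=0.0, origin_y=10.0, cell_size=1.0
    )


def gift_wrap_hull(points: np.ndarray) -> set[tuple[float, float]]:
    """O(n^2) gift-wrapping convex hull; returns the vertex set.

    Independent of the shapely-based implementation under test.  Strictly
    turning, so collinear boundary points are not vertices.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return {tuple(p) for p in pts}
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            if r == p:
                continue
            u, v = pts[q] - pts[p], pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (
                cross == 0
                and np.dot(pts[r] - pts[p], pts[r] - pts[p])
                > np.dot(pts[q] - pts[p], pts[q] - pts[p])
            ):
                q = r
        if q == start:
            break
        hull.append(q)
        if len(hull) > len(pts):
            raise RuntimeError("gift wrap failed to close")
    vertices = {tuple(pts[i]) for i in hull}
    if len(vertices) < 3:
        return vertices
    return vertices
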