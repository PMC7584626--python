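"""Stack binary species ranges into richness maps.

Richness at a cell is simply the number of species whose range raster is
1 there.  Maps are produced for all species and for the diurnal and
nocturnal subsets; because activity labels partition the species pool,
the all-species map equals the per-cell sum of the two group maps.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geodata import AlignmentError, PolygonLayer, RasterGrid
from .ranges import SpeciesRange, rasterize_polygon

logger = logging.getLogger("rangestack")

RICHNESS_NODATA = -1


@dataclass
class RichnessMap:
    """Integer richness raster for one activity group."""

    group: str  # "all" | "diurnal" | "nocturnal"
    raster: RasterGrid
    n_species: int


def mask_array(
    mask: PolygonLayer | np.ndarray | None, grid: RasterGrid
) -> np.ndarray:
    """Resolve a study-area mask to a boolean cell array.

    A polygon layer is rasterized by cell-centre containment of its
    union; ``None`` means every cell is in the study area.
    """
    if mask is None:
        return np.ones(grid.shape, dtype=bool)
    if isinstance(mask, PolygonLayer):
        return rasterize_polygon(mask.union(), grid)
    arr = np.asarray(mask, dtype=bool)
    if arr.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    return arr


def stack_ranges(
    ranges: Sequence[SpeciesRange],
    mask: PolygonLayer | np.ndarray | None,
    grid: RasterGrid,
    group: str = "all",
) -> RichnessMap:
    """Sum binary range rasters into one richness raster.

    Every range raster must be aligned with ``grid``; a misaligned one
    raises :class:`AlignmentError` naming the species.  Cells outside the
    mask are nodata (−1); richness is stored as integers so conservation
    checks (total richness = total range cells) are exact.
    """
    marr = mask_array(mask, grid)
    counts = np.zeros(grid.shape, dtype=np.int32)
    for rng in ranges:
        if not rng.raster.aligned_with(grid):
            raise AlignmentError(
                f"range raster of species {rng.species_id} is not aligned "
                "with the analysis grid"
            )
        counts += (rng.raster.values == 1).astype(np.int32)
    counts[~marr] = RICHNESS_NODATA
    raster = grid.copy_with(counts, nodata=RICHNESS_NODATA)
    return RichnessMap(group=group, raster=raster, n_species=len(ranges))


def group_richness(
    ranges: Sequence[SpeciesRange],
    activity: Mapping[str, str],
    mask: PolygonLayer | np.ndarray | None,
    grid: RasterGrid,
) -> dict[str, RichnessMap]:
    """Build the all/diurnal/nocturnal richness maps in one pass."""
    for rng in ranges:
        if rng.species_id not in activity:
            raise ValueError(f"species {rng.species_id} has no activity label")
        if activity[rng.species_id] not in ("diurnal", "nocturnal"):
            raise ValueError(
                f"species {rng.species_id} has invalid activity "
                f"{activity[rng.species_id]!r}"
            )
    out = {"all": stack_ranges(ranges, mask, grid, "all")}
    for grp in ("diurnal", "nocturnal"):
        subset = [r for r in ranges if activity[r.species_id] == grp]
        out[grp] = stack_ranges(subset, mask, grid, grp)
    return out


def richness_summary(rmap: RichnessMap) -> dict[str, float]:
    """min/max/mean richness and cell count over study-area cells."""
    valid = rmap.raster.valid_mask()
    if not valid.any():
        raise ValueError("no cells inside the study-area mask")
    vals = rmap.raster.values[valid]
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "cells": int(valid.sum()),
    }


def write_summary_csv(maps: Mapping[str, RichnessMap], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "n_species", "min", "max", "mean", "cells"])
        for grp, rmap in maps.items():
            s = richness_summary(rmap)
            writer.writerow(
                [grp, rmap.n_species, int(s["min"]), int(s["max"]),
                 f"{s['mean']:.4f}", s["cells"]]
            )
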