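"""Occurrence cleaning, spatial thinning and activity-group splitting.

Spatial thinning keeps at most one record of each species per analysis
grid cell.  Thinning is cell-based rather than pairwise-distance based:
the analysis grid defines what "one kilometre" means, which makes the
procedure deterministic and consistent with the raster resolution that the
richness maps use.  Within a cell, the first record in input order wins,
so the result is reproducible without a random seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .geodata import OccurrenceRecord, RasterGrid

logger = logging.getLogger("rangestack")

GROUPS = ("all", "diurnal", "nocturnal")


@dataclass
class ThinningReport:
    """Per-species input/retained counts for a thinning pass."""

    per_species: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def total_input(self) -> int:
        return sum(n for n, _ in self.per_species.values())

    @property
    def total_retained(self) -> int:
        return sum(k for _, k in self.per_species.values())

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["species_id", "input_count", "retained_count"])
            for sp in sorted(self.per_species):
                n, k = self.per_species[sp]
                writer.writerow([sp, n, k])


def thin_records(
    records: Sequence[OccurrenceRecord],
    grid: RasterGrid,
) -> tuple[list[OccurrenceRecord], ThinningReport]:
    """Thin each species to at most one record per grid cell.

    Records of different species never suppress one another.  Records
    falling outside the grid extent violate the precondition (upstream
    cleaning should have removed them) and raise ``ValueError``.
    """
    report = ThinningReport()
    seen: set[tuple[str, int, int]] = set()
    retained: list[OccurrenceRecord] = []
    for rec in records:
        cell = grid.point_to_cell(rec.lon, rec.lat)
        if cell is None:
            raise ValueError(
                f"record of {rec.species_id} at ({rec.lon}, {rec.lat}) "
                "falls outside the analysis grid"
            )
        n, k = report.per_species.get(rec.species_id, (0, 0))
        key = (rec.species_id, *cell)
        if key in seen:
            report.per_species[rec.species_id] = (n + 1, k)
            continue
        seen.add(key)
        retained.append(rec)
        report.per_species[rec.species_id] = (n + 1, k + 1)
    logger.info(
        "thinned %d records to %d (%d species)",
        report.total_input, report.total_retained, len(report.per_species),
    )
    return retained, report


def split_by_group(
    records: Sequence[OccurrenceRecord],
) -> dict[str, list[OccurrenceRecord]]:
    """Partition records into {all, diurnal, nocturnal}.

    Activity is a species-level trait here: every record carries its
    label, and diurnal/nocturnal partition the full set exactly.
    """
    out: dict[str, list[OccurrenceRecord]] = {g: [] for g in GROUPS}
    for rec in records:
        if rec.activity not in ("diurnal", "nocturnal"):
            raise ValueError(f"species {rec.species_id} has no valid activity label")
        out["all"].append(rec)
        out[rec.activity].append(rec)
    return out


def species_activity(records: Sequence[OccurrenceRecord]) -> dict[str, str]:
    """Map species_id -> activity, insisting labels are consistent."""
    labels: dict[str, str] = {}
    for rec in records:
        prev = labels.setdefault(rec.species_id, rec.activity)
        if prev != rec.activity:
            raise ValueError(
                f"species {rec.species_id} carries conflicting activity labels"
            )
    return labels


@dataclass(frozen=True)
class ChecklistSummary:
    """Species-level composition of a checklist: counts and percentages."""

    n_species: int
    n_diurnal: int
    n_nocturnal: int
    n_endemic: int

    @property
    def pct_diurnal(self) -> float:
        return 100.0 * self.n_diurnal / self.n_species

    @property
    def pct_nocturnal(self) -> float:
        return 100.0 * self.n_nocturnal / self.n_species

    @property
    def pct_endemic(self) -> float:
        return 100.0 * self.n_endemic / self.n_species


def checklist_summary(records: Sequence[OccurrenceRecord]) -> ChecklistSummary:
    """Species-level diurnal/nocturnal/endemic composition of a record set."""
    activity: dict[str, str] = species_activity(records)
    endemic: dict[str, bool] = {}
    for rec in records:
        endemic.setdefault(rec.species_id, rec.endemic)
    if not activity:
        raise ValueError("no records")
    return ChecklistSummary(
        n_species=len(activity),
        n_diurnal=sum(1 for a in activity.values() if a == "diurnal"),
        n_nocturnal=sum(1 for a in activity.values() if a == "nocturnal"),
        n_endemic=sum(1 for e in endemic.values() if e),
    )
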