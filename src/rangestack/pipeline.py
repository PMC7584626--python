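"""End-to-end orchestration: simulate/load -> thin -> ranges -> richness
-> predictor layers -> driver table, with an output manifest.

The pipeline runs either in synthetic mode (inputs generated from a
scenario seed) or in real-data mode (inputs read from files).  Every
stage writes its artifacts under the output directory and the run ends
with a JSON manifest listing each artifact with a SHA-256 checksum, so
re-runs under the same seed are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import geodata, occurrences, predictors, ranges, richness, synthetic
from .drivers import DriverConfig, DriverTable, build_driver_table, vifstep
from .geodata import ConfigurationError
from .predictors import PREDICTOR_NAMES, VelocityParams, assemble_stack
from .ranges import RangeConfig
from .synthetic import SyntheticScenario

logger = logging.getLogger("rangestack")

STAGES = ("simulate", "thin", "ranges", "richness", "layers", "drivers")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Exactly one of ``scenario`` (synthetic mode) or ``paths`` (real-data
    mode) must be set.  ``paths`` maps input roles (occurrences,
    temperature, precipitation, lgm_temperature, lgm_precipitation,
    fine_dem, ndvi, biomes, mountains, mask) to files; the two LGM roles
    accept a list of files which are averaged.
    """

    out_dir: str = "rangestack-out"
    seed: int = 0
    scenario: SyntheticScenario | None = None
    paths: dict[str, Any] | None = None
    range_config: RangeConfig = field(default_factory=RangeConfig)
    velocity_params: VelocityParams = field(default_factory=VelocityParams)
    driver_config: DriverConfig = field(default_factory=DriverConfig)
    write_true_ranges: bool = False
    write_species_rasters: bool = False

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.paths is None):
            raise ConfigurationError(
                "exactly one of 'scenario' (synthetic) or 'paths' (real data) "
                "must be configured"
            )
        if self.paths is not None:
            for role, value in self.paths.items():
                for p in value if isinstance(value, list) else [value]:
                    if not Path(p).exists():
                        raise ConfigurationError(
                            f"input file for '{role}' not found: {p}"
                        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        def build(klass, key):
            sub = doc.get(key) or {}
            try:
                return klass(**sub)
            except TypeError as exc:
                raise ConfigurationError(f"bad '{key}' block: {exc}") from exc

        kwargs: dict[str, Any] = {
            k: doc[k]
            for k in ("out_dir", "seed", "paths", "write_true_ranges",
                      "write_species_rasters")
            if k in doc
        }
        if "scenario" in doc and doc["scenario"] is not None:
            scen = dict(doc["scenario"])
            scen.setdefault("seed", doc.get("seed", 0))
            kwargs["scenario"] = build_scenario(scen)
        kwargs["range_config"] = build(RangeConfig, "range_config")
        kwargs["velocity_params"] = build(VelocityParams, "velocity_params")
        kwargs["driver_config"] = build(DriverConfig, "driver_config")
        return cls(**kwargs)


def build_scenario(spec: dict) -> SyntheticScenario:
    try:
        return SyntheticScenario(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in spec.items()
        })
    except TypeError as exc:
        raise ConfigurationError(f"bad scenario block: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[Path] = []
        self.counts: dict[str, Any] = {}
        self.failures: dict[str, str] = {}
        self.landscape: synthetic.Landscape | None = None
        self.records = None
        self.thinned = None
        self.species_ranges: list[ranges.SpeciesRange] = []
        self.richness_maps: dict[str, richness.RichnessMap] = {}
        self.stack: predictors.PredictorStack | None = None
        self.driver_table: DriverTable | None = None

    def add(self, path: Path) -> None:
        self.artifacts.append(path)


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    if cfg.scenario is not None:
        scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
        land = synthetic.make_landscape(scenario)
        truth, records = synthetic.make_species_pool(scenario, land)
        run.landscape = land
        run.records = records
        run.truth = truth
        inputs = run.out / "inputs"
        inputs.mkdir(exist_ok=True)
        geodata.write_occurrence_table(records, inputs / "occurrences.csv")
        run.add(inputs / "occurrences.csv")
        for name in ("temperature", "precipitation", "ndvi",
                     "lgm_temperature", "lgm_precipitation", "fine_dem"):
            geodata.write_raster(getattr(land, name), inputs / f"{name}.asc")
            run.add(inputs / f"{name}.asc")
        geodata.write_polygon_layer(land.biomes, inputs / "biomes.geojson")
        geodata.write_polygon_layer(land.mountains, inputs / "mountains.geojson")
        geodata.write_polygon_layer(land.mask_polygon, inputs / "mask.geojson")
        for f in ("biomes.geojson", "mountains.geojson", "mask.geojson"):
            run.add(inputs / f)
        truth_dir = run.out / "truth"
        truth_dir.mkdir(exist_ok=True)
        with open(truth_dir / "true_beta.csv", "w") as fh:
            fh.write("term,beta\n")
            fh.write(f"intercept,{scenario.glm_truth[0]!r}\n")
            for name, b in zip(PREDICTOR_NAMES, scenario.glm_truth[1:]):
                fh.write(f"{name},{b!r}\n")
        run.add(truth_dir / "true_beta.csv")
        if cfg.write_true_ranges:
            for tr in truth:
                g = land.grid.copy_with(tr.cells.astype(np.int16), nodata=-1)
                geodata.write_raster(g, truth_dir / f"{tr.species_id}.asc")
                run.add(truth_dir / f"{tr.species_id}.asc")
        run.counts["species_simulated"] = len(truth)
        run.counts["occurrences_simulated"] = len(records)
    else:
        run.landscape = _load_real_inputs(run)


def _load_real_inputs(run: _Run) -> synthetic.Landscape:
    paths = run.config.paths
    assert paths is not None

    def raster(role):
        return geodata.read_raster(paths[role])

    def averaged(role):
        value = paths[role]
        files = value if isinstance(value, list) else [value]
        return predictors.average_rasters([geodata.read_raster(p) for p in files])

    temp = raster("temperature")
    biomes = geodata.read_polygon_layer(paths["biomes"], "biome_id")
    mask_layer = (
        geodata.read_polygon_layer(paths["mask"])
        if "mask" in paths
        else geodata.PolygonLayer([(biomes.union(), {"name": "biome-union"})])
    )
    records, log = geodata.read_occurrence_table(paths["occurrences"])
    run.records = records
    run.counts["occurrence_rejections"] = dataclasses.asdict(log)
    return synthetic.Landscape(
        grid=temp.copy_with(np.zeros(temp.shape)),
        temperature=temp,
        precipitation=raster("precipitation"),
        ndvi=raster("ndvi"),
        lgm_temperature=averaged("lgm_temperature"),
        lgm_precipitation=averaged("lgm_precipitation"),
        dem=temp,  # coarse DEM unused; heterogeneity comes from fine_dem
        fine_dem=raster("fine_dem"),
        biomes=biomes,
        mountains=geodata.read_polygon_layer(paths["mountains"], "uplift_age_myr"),
        mask_polygon=mask_layer,
        mask=richness.mask_array(mask_layer, temp.copy_with(np.zeros(temp.shape))),
    )


def _stage_thin(run: _Run) -> None:
    land = run.landscape
    thinned, report = occurrences.thin_records(run.records, land.grid)
    run.thinned = thinned
    geodata.write_occurrence_table(thinned, run.out / "thinned_occurrences.csv")
    report.write_csv(run.out / "thinning_report.csv")
    run.add(run.out / "thinned_occurrences.csv")
    run.add(run.out / "thinning_report.csv")
    run.counts["records_before_thinning"] = report.total_input
    run.counts["records_after_thinning"] = report.total_retained


def _stage_ranges(run: _Run) -> None:
    land = run.landscape
    cfg = run.config
    by_species: dict[str, list] = {}
    for rec in run.thinned:
        by_species.setdefault(rec.species_id, []).append(rec)
    out_dir = run.out / "ranges"
    if cfg.write_species_rasters:
        out_dir.mkdir(exist_ok=True)
    for sp in sorted(by_species):
        try:
            rng = ranges.build_range(
                by_species[sp], land.biomes, land.temperature, land.grid,
                cfg.range_config, mask=land.mask,
            )
        except ValueError as exc:
            run.failures[sp] = str(exc)
            logger.warning("species %s dropped: %s", sp, exc)
            continue
        run.species_ranges.append(rng)
        if cfg.write_species_rasters:
            geodata.write_raster(rng.raster, out_dir / f"{sp}.asc")
            run.add(out_dir / f"{sp}.asc")
    run.counts["species_ranged"] = len(run.species_ranges)
    run.counts["species_failed"] = len(run.failures)


def _stage_richness(run: _Run) -> None:
    land = run.landscape
    activity = occurrences.species_activity(run.thinned)
    run.richness_maps = richness.group_richness(
        run.species_ranges, activity, land.mask, land.grid
    )
    for grp, rmap in run.richness_maps.items():
        geodata.write_raster(rmap.raster, run.out / f"richness_{grp}.asc")
        run.add(run.out / f"richness_{grp}.asc")
    richness.write_summary_csv(run.richness_maps, run.out / "richness_summary.csv")
    run.add(run.out / "richness_summary.csv")


def _stage_layers(run: _Run) -> None:
    land = run.landscape
    vp = run.config.velocity_params
    layers = {
        "temperature": land.temperature,
        "precipitation": land.precipitation,
        "ndvi": land.ndvi,
        "temperature_velocity": predictors.climate_velocity(
            land.temperature, land.lgm_temperature, vp
        ),
        "precipitation_velocity": predictors.climate_velocity(
            land.precipitation, land.lgm_precipitation, vp
        ),
        "topo_heterogeneity": predictors.topo_heterogeneity(land.fine_dem, land.grid),
        "uplift_age": predictors.rasterize_uplift(land.mountains, land.grid),
    }
    # predictors are analysed within the study area only
    for name in ("topo_heterogeneity", "uplift_age"):
        vals = layers[name].values.astype(float, copy=True)
        vals[~land.mask] = layers[name].nodata
        layers[name] = land.grid.copy_with(vals, nodata=layers[name].nodata)
    run.stack = assemble_stack(layers)
    layer_dir = run.out / "layers"
    layer_dir.mkdir(exist_ok=True)
    for name, g in layers.items():
        geodata.write_raster(g, layer_dir / f"{name}.asc")
        run.add(layer_dir / f"{name}.asc")


def _stage_drivers(run: _Run) -> None:
    cfg = run.config
    stack = run.stack
    X = stack.to_matrix()
    report = vifstep(X, cfg.driver_config.vif_threshold, PREDICTOR_NAMES)
    report.write_csv(run.out / "vif_report.csv")
    run.add(run.out / "vif_report.csv")
    run.counts["vif_removed"] = report.removal_sequence
    run.driver_table = build_driver_table(
        run.richness_maps, stack, cfg.driver_config
    )
    geodata.write_driver_table(run.driver_table, run.out / "driver_table.csv")
    run.add(run.out / "driver_table.csv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "thin": _stage_thin,
    "ranges": _stage_ranges,
    "richness": _stage_richness,
    "layers": _stage_layers,
    "drivers": _stage_drivers,
}


def run_pipeline(
    config: PipelineConfig, through: str = "drivers"
) -> dict:
    """Run the pipeline from the start through stage ``through``.

    Returns the manifest (also written as ``manifest.json``): artifact
    checksums, per-stage record counts, and the per-species failure log,
    so no species is ever silently dropped.
    """
    if through not in STAGES:
        raise ConfigurationError(f"unknown stage '{through}'")
    run = _Run(config)
    last = STAGES.index(through)
    for stage in STAGES[: last + 1]:
        logger.info("=== stage %s ===", stage)
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:  # noqa: BLE001 - wrapped with stage name
            raise StageError(stage, exc) from exc
    manifest = {
        "seed": config.seed,
        "mode": "synthetic" if config.scenario is not None else "real",
        "stages_run": list(STAGES[: last + 1]),
        "counts": run.counts,
        "species_failures": run.failures,
        "artifacts": {
            str(p.relative_to(run.out)): _sha256(p) for p in run.artifacts
        },
    }
    (run.out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["_run"] = run  # in-memory handles for library callers
    return manifest
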