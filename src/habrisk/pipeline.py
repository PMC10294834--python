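"""Configuration-driven orchestration of the full habitat-risk analysis.

``run_all`` executes the stages in order — terrain derivatives,
occurrence preparation, collinearity screening, one random-forest SDM
per species, the habitat-map union, and the downstream risk statistics —
writing every intermediate artifact into a run directory together with a
machine-readable manifest (package version, config hash, seeds, and the
complete list of outputs). Re-running with an identical config
reproduces the outputs; completed stages are skipped unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geodata import (
    Grid,
    PointSet,
    PredictorStack,
    rasterize_lines,
    rasterize_polygons,
    read_geojson,
    read_points_csv,
    read_raster,
    write_points_csv,
    write_raster,
)
from .occurrence import sample_pseudo_absences, thin_to_pixel
from .risk import (
    build_region_table,
    cover_composition,
    park_risk_ratio,
    spearman,
    trail_overlap,
    union_maps,
)
from .screening import screen_collinear
from .sdm import (
    RandomForestSDM,
    binarize,
    make_dataset,
    median_importance,
    predict_surface,
    response_curve,
)
from .terrain import TerrainParams, slope, tpi

log = logging.getLogger("habrisk")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Everything one analysis run needs, loadable from YAML."""

    dem: str
    mask: str
    occurrences: str
    species: list[str]
    layers: dict[str, str] = field(default_factory=dict)
    regions: str | None = None          # GeoJSON polygons with id/name props
    incidents: str | None = None        # CSV: id,name,population,snakebites
    trails: str | None = None           # GeoJSON LineStrings
    parks: str | None = None            # GeoJSON polygons with id/name props
    cover_layers: list[str] = field(default_factory=lambda: ["forest", "herbaceous"])
    tpi_radius: int = 1
    n_pseudo: int = 10000
    train_frac: float = 0.7
    cv_folds: int = 10
    n_trees: int = 1000
    corr_threshold: float = 0.75
    seed: int = 42
    species_seeds: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    def seed_for(self, species: str) -> int:
        if species in self.species_seeds:
            return int(self.species_seeds[species])
        i = self.species.index(species)
        return (self.seed + 7919 * (i + 1)) % (2**31 - 1)

    def validate_paths(self) -> None:
        paths = [self.dem, self.mask, self.occurrences, *self.layers.values()]
        paths += [p for p in (self.regions, self.incidents, self.trails, self.parks) if p]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing paths: {missing}")


class _Stage:
    """Records outputs and supports resume-if-complete semantics."""

    def __init__(self, name: str, out_dir: Path, manifest: dict, force: bool):
        self.name = name
        self.out_dir = out_dir
        self.manifest = manifest
        self.force = force
        self.t0 = 0.0

    def outputs(self) -> list[Path]:
        return [self.out_dir / f for f in self.manifest["stages"].get(self.name, [])]

    def complete(self, expected: list[str]) -> bool:
        if self.force:
            return False
        return all((self.out_dir / f).exists() for f in expected)

    def record(self, files: list[str], seconds: float) -> None:
        self.manifest["stages"][self.name] = sorted(files)
        self.manifest["timings_s"][self.name] = round(seconds, 3)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


def run_all(config: RunConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Run the full analysis; returns the run directory.

    Any stage failure raises with the stage name attached. Completed
    stages (all expected outputs present) are skipped unless ``force``.
    """
    config.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "species_seeds": {s: config.seed_for(s) for s in config.species},
        "stages": {},
        "timings_s": {},
    }

    stage = None
    try:
        # ---- terrain -----------------------------------------------------
        stage = "terrain"
        t0 = time.perf_counter()
        dem = read_raster(config.dem)
        slope_path, tpi_path = out / "slope.asc", out / "tpi.asc"
        if force or not (slope_path.exists() and tpi_path.exists()):
            log.info("terrain: slope + TPI (radius=%d)", config.tpi_radius)
            write_raster(slope(dem), slope_path)
            write_raster(tpi(dem, TerrainParams(config.tpi_radius)), tpi_path)
        slope_g, tpi_g = read_raster(slope_path), read_raster(tpi_path)
        manifest["stages"]["terrain"] = ["slope.asc", "tpi.asc"]
        manifest["timings_s"]["terrain"] = round(time.perf_counter() - t0, 3)

        layers = {"elevation": dem, "tpi": tpi_g, "slope": slope_g}
        for name, path in config.layers.items():
            layers[name] = read_raster(path)
        stack = PredictorStack(list(layers), layers)
        mask = read_raster(config.mask)

        # ---- occurrence preparation ---------------------------------------
        stage = "occurrences"
        t0 = time.perf_counter()
        occ_files = []
        datasets = {}
        for sp in config.species:
            seed = config.seed_for(sp)
            pres_path = out / f"presences_{sp}.csv"
            absn_path = out / f"pseudo_absences_{sp}.csv"
            if force or not (pres_path.exists() and absn_path.exists()):
                log.info("occurrences: %s (seed=%d)", sp, seed)
                raw = read_points_csv(config.occurrences, species=sp)
                pres = thin_to_pixel(raw, dem.spec, seed=seed)
                pseudo = sample_pseudo_absences(
                    mask, config.n_pseudo, seed=seed, exclude=pres
                )
                write_points_csv(pres, pres_path)
                write_points_csv(
                    PointSet(sp, pseudo.coords, pseudo.labels), absn_path
                )
            pres = read_points_csv(pres_path)
            pseudo = read_points_csv(absn_path)
            datasets[sp] = make_dataset(stack, pres, pseudo)
            occ_files += [pres_path.name, absn_path.name]
        manifest["stages"]["occurrences"] = sorted(occ_files)
        manifest["timings_s"]["occurrences"] = round(time.perf_counter() - t0, 3)

        # ---- screening -----------------------------------------------------
        stage = "screening"
        t0 = time.perf_counter()
        screen_sp = max(datasets, key=lambda s: int((datasets[s].y == 1).sum()))
        log.info("screening on %s dataset (threshold=%.2f)",
                 screen_sp, config.corr_threshold)
        report = screen_collinear(
            datasets[screen_sp].X, datasets[screen_sp].y,
            threshold=config.corr_threshold,
        )
        (out / "screening.json").write_text(json.dumps(report.to_dict(), indent=2))
        report.to_frame().to_csv(out / "screening_correlations.csv", index=False)
        manifest["stages"]["screening"] = [
            "screening.json", "screening_correlations.csv",
        ]
        manifest["timings_s"]["screening"] = round(time.perf_counter() - t0, 3)
        retained = report.retained

        # ---- per-species SDM -------------------------------------------------
        stage = "sdm"
        t0 = time.perf_counter()
        sdm_files = []
        models = {}
        binaries = []
        model_stack = stack.subset(retained)
        for sp in config.species:
            seed = config.seed_for(sp)
            log.info("sdm: %s (n_trees=%d, seed=%d)", sp, config.n_trees, seed)
            ds = datasets[sp]
            model = RandomForestSDM(
                n_trees=config.n_trees, train_frac=config.train_frac,
                cv_folds=config.cv_folds, species=sp, random_state=seed,
            ).fit(ds.X[retained], ds.y)
            models[sp] = model
            (out / f"sdm_report_{sp}.json").write_text(
                json.dumps(model.report_.to_dict(), indent=2)
            )
            model.importance_.to_csv(out / f"importance_{sp}.csv")
            surf = predict_surface(model, model_stack)
            binary = binarize(surf, model.threshold_)
            write_raster(surf, out / f"suitability_{sp}.asc")
            write_raster(binary, out / f"binary_{sp}.asc")
            binaries.append(binary)
            sdm_files += [
                f"sdm_report_{sp}.json", f"importance_{sp}.csv",
                f"suitability_{sp}.asc", f"binary_{sp}.asc",
            ]

        med = median_importance({sp: m.importance_ for sp, m in models.items()})
        med.to_csv(out / "importance_median.csv")
        sdm_files.append("importance_median.csv")
        top3 = list(med.index[med["top"]])
        curve_rows = []
        for sp, model in models.items():
            for var in top3:
                rc = response_curve(model, datasets[sp].X[retained], var)
                curve_rows.append(pd.DataFrame({
                    "species": sp, "variable": var,
                    "value": rc.grid, "probability": rc.probability,
                }))
        pd.concat(curve_rows, ignore_index=True).to_csv(
            out / "response_curves.csv", index=False
        )
        sdm_files.append("response_curves.csv")
        manifest["stages"]["sdm"] = sorted(sdm_files)
        manifest["timings_s"]["sdm"] = round(time.perf_counter() - t0, 3)

        # ---- union ------------------------------------------------------------
        stage = "union"
        t0 = time.perf_counter()
        union = union_maps(binaries)
        write_raster(union, out / "habitat_union.asc")
        manifest["stages"]["union"] = ["habitat_union.asc"]
        manifest["timings_s"]["union"] = round(time.perf_counter() - t0, 3)

        # ---- risk ---------------------------------------------------------------
        stage = "risk"
        t0 = time.perf_counter()
        risk_files = []
        summary: dict = {
            "habitat_fraction": float(
                (union.values[union.valid()] == 1).mean()
            ),
            "habitat_area_km2": float(
                (union.values == 1).sum() * union.spec.cell_area() / 1e6
            ),
        }
        trail_grid = None
        if config.trails:
            trail_lines = [
                list(geom.coords) for _, geom in read_geojson(config.trails)
            ]
            trail_grid = rasterize_lines(trail_lines, union.spec)
            write_raster(trail_grid, out / "trails.asc")
            risk_files.append("trails.asc")
        if config.regions and config.incidents:
            feats = read_geojson(config.regions)
            region_grid = rasterize_polygons(
                [(int(p["id"]), g) for p, g in feats], union.spec
            )
            info = pd.read_csv(config.incidents)
            table = build_region_table(union, region_grid, info, trail_grid)
            table.to_csv(out / "region_table.csv", index=False)
            risk_files.append("region_table.csv")
            ok = table["habitat_proportion"].notna()
            corr = spearman(
                table.loc[ok, "habitat_proportion"],
                table.loc[ok, "incidence_per_10k"],
            )
            summary["spearman_rho"] = corr.rho
            summary["spearman_p"] = corr.p_value
            summary["spearman_n"] = corr.n
        if config.parks:
            park_feats = read_geojson(config.parks)
            parks = {}
            for i, (props, geom) in enumerate(park_feats, start=1):
                pid = int(props.get("id", i))
                mask_g = rasterize_polygons([(pid, geom)], union.spec)
                entry = {"risk_ratio": park_risk_ratio(union, mask_g)}
                if trail_grid is not None:
                    entry["trail_overlap"] = trail_overlap(union, trail_grid, mask_g)
                parks[props.get("name", f"park_{pid}")] = entry
            summary["parks"] = parks
        if trail_grid is not None:
            summary["trail_overlap_total"] = trail_overlap(union, trail_grid)
        cover_names = [n for n in config.cover_layers if n in stack]
        if cover_names:
            comp = cover_composition(union, stack.subset(cover_names))
            summary["cover_composition"] = {k: float(v) for k, v in comp.items()}
        def _denan(obj):
            if isinstance(obj, dict):
                return {k: _denan(v) for k, v in obj.items()}
            if isinstance(obj, float) and np.isnan(obj):
                return None
            return obj

        (out / "risk_summary.json").write_text(json.dumps(_denan(summary), indent=2))
        risk_files.append("risk_summary.json")
        manifest["stages"]["risk"] = sorted(risk_files)
        manifest["timings_s"]["risk"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # rasters carry a .prj sidecar; declare those too so the manifest lists
    # every file the run wrote
    for files in manifest["stages"].values():
        files += [f[:-4] + ".prj" for f in list(files) if f.endswith(".asc")]
        files.sort()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %s", out)
    return out
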