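"""Synthetic study systems for end-to-end testing of the habitat-risk
pipeline.

The generator emulates the statistical structure the analysis assumes,
at desk scale: a smooth random-field DEM; a temperature layer that is a
lapse-rate function of elevation plus noise (so temperature and
elevation are strongly collinear, |r| > 0.75, giving the collinearity
screen real work); four percent-cover layers with an engineered
herbaceous-shrubland collinear pair; three pit-viper-like species whose
true habitat suitability prefers valley positions (negative topographic
position index), moderate slopes near an optimum, and species-specific
temperature windows; presence points sampled proportional to true
suitability; rectangular administrative regions with log-uniform
populations and Poisson snakebite counts whose rate increases with the
region's true habitat proportion; and valley-biased hiking trails plus
rectangular park polygons.

Every output is a deterministic function of (config, seed); the
generator records its true parameters so recovery tests have an answer
key.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .geodata import Grid, GridSpec, PointSet, PredictorStack
from .terrain import TerrainParams, slope, tpi

__all__ = [
    "SpeciesParams",
    "SynthConfig",
    "StudySystem",
    "gen_dem",
    "gen_climate",
    "gen_covers",
    "true_suitability",
    "sample_presences",
    "gen_regions_and_incidents",
    "gen_trails_and_parks",
    "generate_study_system",
    "write_study_system",
    "default_species",
    "lag1_autocorrelation",
]


@dataclass(frozen=True)
class SpeciesParams:
    """True response-surface parameters of a synthetic species.

    The suitability logit combines a linear valley preference
    (tpi_coefficient < 0), a Gaussian bump around a slope optimum, and a
    plateau temperature window with logistic shoulders: occurrence
    probability rises sharply at temp_window[0] and falls sharply at
    temp_window[1].
    """

    name: str
    temp_window: tuple[float, float]   # deg C
    tpi_coefficient: float = -1.2      # per m of TPI; negative = valleys
    slope_optimum: float = 15.0        # degrees
    slope_width: float = 6.0           # degrees
    baseline_logit: float = -8.0
    temp_amplitude: float = 7.0
    temp_shoulder: float = 0.5         # deg C softness of the window edges
    slope_amplitude: float = 3.0

    def __post_init__(self) -> None:
        if not self.temp_window[0] < self.temp_window[1]:
            raise ValueError("temp_window must satisfy low < high")
        if self.slope_width <= 0:
            raise ValueError("slope_width must be positive")
        if self.tpi_coefficient >= 0:
            raise ValueError("tpi_coefficient must be negative (valley preference)")


def default_species() -> list[SpeciesParams]:
    """Three Gloydius-like species differing mainly by temperature window.

    A warm-window lowland species, a broad-window widespread species, and
    a cool-window highland species; presence counts elsewhere default to
    700 / 1500 / 100 in the same order.
    """
    return [
        SpeciesParams("G_brevicaudus", temp_window=(18.0, 20.0)),
        SpeciesParams("G_ussuriensis", temp_window=(14.0, 19.0)),
        SpeciesParams("G_saxatilis", temp_window=(13.0, 17.0)),
    ]


@dataclass
class SynthConfig:
    """Generator configuration; defaults define the study conditions."""

    n_rows: int = 256
    n_cols: int = 256
    cell_size: float = 30.0
    seed: int = 0
    # terrain
    dem_smoothness: float = 16.0       # coarse-relief Gaussian sigma in cells
    dem_relief_fraction: float = 0.2   # fine-relief amplitude relative to coarse
    dem_macro_fraction: float = 1.0    # region-scale relief amplitude (sigma x4)
    dem_range: tuple[float, float] = (50.0, 1200.0)
    tpi_radius: int = 1
    # climate
    sea_level_temp: float = 22.0       # deg C
    lapse_rate: float = 0.0065         # deg C per m
    temp_noise_sd: float = 0.75        # deg C
    precip_range: tuple[float, float] = (900.0, 1600.0)
    min_temp_dem_r: float = 0.78
    # covers
    herb_climate_loading: float = 0.65  # herbaceous loading on the greenness window
    herb_window: tuple[float, float] = (12.0, 19.5)  # deg C growing-season band
    herb_window_shoulder: float = 1.2
    shrub_mult: float = 0.85
    shrub_noise_sd: float = 9.0         # percent points
    min_cover_pair_r: float = 0.78
    # sampling
    presence_counts: dict[str, int] = field(
        default_factory=lambda: {
            "G_brevicaudus": 700, "G_ussuriensis": 1500, "G_saxatilis": 100,
        }
    )
    n_pseudo_absences: int = 10000
    # regions / incidents
    n_regions: int = 16
    population_range: tuple[float, float] = (2e5, 5e6)  # log-uniform
    incident_intercept: float = 0.3    # per 10,000 people
    incident_slope: float = 4.0        # per 10,000 per unit habitat proportion
    # trails / parks
    n_trails: int = 8
    trail_steps: int = 400
    trail_valley_bias: float = 1.0     # weight = exp(-bias * TPI)
    n_parks: int = 6
    park_side_range: tuple[int, int] = (12, 40)  # cells; area >= 100 cells

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows, n_cols=self.n_cols,
            origin_x=0.0, origin_y=self.n_rows * self.cell_size,
            cell_size=self.cell_size, crs_tag="synthetic-local",
        )


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field (white noise if sigma=0)."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = gaussian_filter(z, sigma=sigma, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def _rescale(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:
        return np.full_like(z, (lo + hi) / 2)
    return lo + (z - zmin) * (hi - lo) / (zmax - zmin)


def lag1_autocorrelation(values: np.ndarray) -> float:
    """Mean of row- and column-wise lag-1 autocorrelation of a field."""
    a = np.corrcoef(values[:, :-1].ravel(), values[:, 1:].ravel())[0, 1]
    b = np.corrcoef(values[:-1, :].ravel(), values[1:, :].ravel())[0, 1]
    return float((a + b) / 2)


# ---------------------------------------------------------------------------
# Landscape layers
# ---------------------------------------------------------------------------

def gen_dem(config: SynthConfig, rng: np.random.Generator | None = None) -> Grid:
    """Multi-scale correlated random-field DEM within the configured range.

    Three superposed Gaussian random fields: a macro component (sigma =
    4 x dem_smoothness) that differentiates whole provinces the way a
    mountain range does, a coarse component (sigma = dem_smoothness)
    carrying mountain-scale relief, and a fine component (sigma an eighth
    of that) adding local relief — so valley positions occur at every
    elevation the way they do in real terrain, keeping the topographic
    position index largely decoupled from absolute elevation while
    regions still differ genuinely in elevation and climate.
    """
    if config.n_rows < 64 or config.n_cols < 64:
        raise ValueError("DEM generation expects at least a 64x64 grid")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    macro = _smooth_field(rng, shape, config.dem_smoothness * 4.0)
    coarse = _smooth_field(rng, shape, config.dem_smoothness)
    fine = _smooth_field(rng, shape, config.dem_smoothness / 8.0)
    z = (
        config.dem_macro_fraction * macro
        + coarse
        + config.dem_relief_fraction * fine
    )
    return Grid(config.grid_spec(), _rescale(z, *config.dem_range))


def gen_climate(
    dem: Grid, config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[Grid, Grid]:
    """Temperature (lapse-rate function of elevation + smooth noise) and an
    independent smooth precipitation field.

    The noise draw is repeated up to 5 times if |pearson(temp, elev)|
    drops below the configured floor (0.75 by default).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    z = dem.values
    base = config.sea_level_temp - config.lapse_rate * z
    for _ in range(5):
        noise = _smooth_field(rng, z.shape, config.dem_smoothness / 2)
        temp = base + config.temp_noise_sd * noise
        r = np.corrcoef(temp.ravel(), z.ravel())[0, 1]
        if abs(r) > config.min_temp_dem_r:
            break
    else:
        raise RuntimeError(
            f"could not reach |r(temp, elevation)| > {config.min_temp_dem_r}; "
            "reduce temp_noise_sd"
        )
    precip = _rescale(
        _smooth_field(rng, z.shape, config.dem_smoothness), *config.precip_range
    )
    return Grid(dem.spec, temp), Grid(dem.spec, precip)


def gen_covers(
    dem: Grid,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    temperature: Grid | None = None,
) -> dict[str, Grid]:
    """Percent-cover layers: bare, herbaceous, shrubland, forest (0-100).

    Herbaceous cover tracks a generic growing-season temperature window
    (grassland thrives in a mid-temperature band) with a moderate loading,
    so it carries genuine marginal signal through the climate path while
    its correlation with raw temperature stays below the screening
    threshold; shrubland is a monotone function of herbaceous plus noise,
    making the pair strongly collinear (|r| > 0.78) with shrubland the
    weaker, attenuated copy. Forest and bare are independent smooth
    fields. When no temperature layer is supplied, the lapse-rate
    transform of the DEM stands in for it.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    shape = dem.values.shape
    climate = (
        temperature.values
        if temperature is not None
        else config.sea_level_temp - config.lapse_rate * dem.values
    )
    greenness = _window_term(
        climate, *config.herb_window, config.herb_window_shoulder
    )
    zs = (greenness - greenness.mean()) / greenness.std()
    a = config.herb_climate_loading
    for _ in range(5):
        herb_core = a * zs + np.sqrt(1 - a**2) * _smooth_field(
            rng, shape, config.dem_smoothness
        )
        herb = np.clip(_rescale(herb_core, 0.0, 100.0), 0.0, 100.0)
        shrub = np.clip(
            config.shrub_mult * herb + 5.0
            + config.shrub_noise_sd * rng.standard_normal(shape),
            0.0, 100.0,
        )
        r = np.corrcoef(herb.ravel(), shrub.ravel())[0, 1]
        if abs(r) > config.min_cover_pair_r:
            break
    else:
        raise RuntimeError("herbaceous-shrubland correlation floor not reached")
    bare = np.clip(
        _rescale(_smooth_field(rng, shape, config.dem_smoothness), 0.0, 30.0), 0, 100
    )
    forest = np.clip(
        _rescale(_smooth_field(rng, shape, config.dem_smoothness), 20.0, 90.0), 0, 100
    )
    return {
        "bare": Grid(dem.spec, bare),
        "herbaceous": Grid(dem.spec, herb),
        "shrubland": Grid(dem.spec, shrub),
        "forest": Grid(dem.spec, forest),
    }


# ---------------------------------------------------------------------------
# Species truth and sampling
# ---------------------------------------------------------------------------

def _window_term(temp: np.ndarray, low: float, high: float, shoulder: float) -> np.ndarray:
    """Plateau in (low, high) with logistic shoulders, in (0, 1)."""
    rise = 1.0 / (1.0 + np.exp(-(temp - low) / shoulder))
    fall = 1.0 / (1.0 + np.exp((temp - high) / shoulder))
    return rise * fall


def true_suitability(stack: PredictorStack, params: SpeciesParams) -> Grid:
    """True occurrence probability surface for a synthetic species."""
    for layer in ("tpi", "slope", "temperature"):
        if layer not in stack:
            raise KeyError(f"stack is missing required layer {layer!r}")
    t = stack["tpi"].values
    s = stack["slope"].values
    temp = stack["temperature"].values
    logit = (
        params.baseline_logit
        + params.tpi_coefficient * t
        + params.slope_amplitude
        * np.exp(-((s - params.slope_optimum) ** 2) / (2 * params.slope_width**2))
        + params.temp_amplitude
        * _window_term(temp, *params.temp_window, params.temp_shoulder)
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    return Grid(stack.spec, p)


def sample_presences(
    suitability: Grid, n: int, seed: int | np.random.Generator,
    species: str = "species",
) -> PointSet:
    """Draw n distinct cells with probability proportional to suitability;
    points sit at cell centers."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    valid = suitability.valid()
    flat = np.flatnonzero(valid.ravel())
    if n > len(flat):
        raise ValueError(f"cannot draw {n} presences from {len(flat)} cells")
    w = suitability.values.ravel()[flat].astype(float)
    w = np.maximum(w, 0)
    if w.sum() <= 0:
        raise ValueError("suitability surface has no positive mass")
    chosen = rng.choice(flat, size=n, replace=False, p=w / w.sum())
    row, col = np.divmod(chosen, suitability.spec.n_cols)
    x, y = suitability.spec.center_of(row, col)
    return PointSet(species, np.column_stack([x, y]), np.ones(n, dtype=int))


# ---------------------------------------------------------------------------
# Regions, incidents, trails, parks
# ---------------------------------------------------------------------------

def _region_tiling(k: int) -> tuple[int, int]:
    """Factor k into the most square (rows, cols) tiling."""
    best = (1, k)
    for r in range(1, int(np.sqrt(k)) + 1):
        if k % r == 0:
            best = (r, k // r)
    return best


def gen_regions_and_incidents(
    spec: GridSpec,
    habitat_union: Grid,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Grid, pd.DataFrame]:
    """Rectangular regions tiling the grid, with populations and Poisson
    snakebite counts whose rate rises with the region's habitat proportion.

    counts ~ Poisson(population * (a + b * habitat_proportion) / 10^4).
    Returns the region label grid and a table (id, name, population,
    snakebites, true_habitat_proportion, true_rate_per_10k).
    """
    k = config.n_regions
    if k < 4:
        raise ValueError("need at least 4 regions")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    kr, kc = _region_tiling(k)
    row_edges = np.linspace(0, spec.n_rows, kr + 1).astype(int)
    col_edges = np.linspace(0, spec.n_cols, kc + 1).astype(int)
    labels = np.zeros(spec.shape)
    rows = []
    rid = 0
    lo, hi = config.population_range
    for i in range(kr):
        for j in range(kc):
            rid += 1
            sl = (slice(row_edges[i], row_edges[i + 1]),
                  slice(col_edges[j], col_edges[j + 1]))
            labels[sl] = rid
            m = habitat_union.valid()[sl]
            prop = (
                float((habitat_union.values[sl][m] == 1).mean()) if m.any() else 0.0
            )
            pop = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rate = config.incident_intercept + config.incident_slope * prop
            count = int(rng.poisson(pop * rate / 1e4))
            rows.append(
                {
                    "id": rid,
                    "name": f"region_{rid:02d}",
                    "population": pop,
                    "snakebites": count,
                    "true_habitat_proportion": prop,
                    "true_rate_per_10k": rate,
                }
            )
    return Grid(spec, labels), pd.DataFrame(rows)


def gen_trails_and_parks(
    tpi_grid: Grid,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[list[tuple[float, float]]], list]:
    """Valley-biased random-walk trails and rectangular park polygons.

    Each trail step moves to one of the 8 neighbors with probability
    proportional to exp(-bias * TPI(neighbor)), so trails descend toward
    valley positions. Parks are axis-aligned rectangles of at least 100
    cells, fully inside the grid.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    spec = tpi_grid.spec
    t = np.where(tpi_grid.valid(), tpi_grid.values, np.inf)
    moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    trails = []
    for _ in range(config.n_trails):
        r = int(rng.integers(0, spec.n_rows))
        c = int(rng.integers(0, spec.n_cols))
        path = [(r, c)]
        for _ in range(config.trail_steps):
            cand, w = [], []
            for dr, dc in moves:
                rr, cc = r + dr, c + dc
                if 0 <= rr < spec.n_rows and 0 <= cc < spec.n_cols and np.isfinite(t[rr, cc]):
                    cand.append((rr, cc))
                    w.append(np.exp(-config.trail_valley_bias * t[rr, cc]))
            if not cand:
                break
            w = np.asarray(w)
            r, c = cand[int(rng.choice(len(cand), p=w / w.sum()))]
            path.append((r, c))
        xs, ys = spec.center_of(
            np.array([p[0] for p in path]), np.array([p[1] for p in path])
        )
        trails.append(list(zip(xs.tolist(), ys.tolist())))

    parks = []
    lo, hi = config.park_side_range
    for _ in range(config.n_parks):
        for _ in range(100):  # retry until area >= 100 cells (usually first try)
            h = int(rng.integers(lo, hi + 1))
            w_ = int(rng.integers(lo, hi + 1))
            if h * w_ >= 100:
                break
        r0 = int(rng.integers(0, max(spec.n_rows - h, 1)))
        c0 = int(rng.integers(0, max(spec.n_cols - w_, 1)))
        x0 = spec.origin_x + c0 * spec.cell_size
        y1 = spec.origin_y - r0 * spec.cell_size
        parks.append(
            box(x0, y1 - h * spec.cell_size, x0 + w_ * spec.cell_size, y1)
        )
    return trails, parks


# ---------------------------------------------------------------------------
# Full system
# ---------------------------------------------------------------------------

@dataclass
class StudySystem:
    """A complete synthetic study system plus its answer key."""

    config: SynthConfig
    stack: PredictorStack                 # all candidate predictors
    mask: Grid                            # 1 = analyzable land
    species: list[SpeciesParams]
    suitability: dict[str, Grid]          # true per-species probability
    presences: dict[str, PointSet]
    true_union: Grid                      # OR of thresholded true suitabilities
    regions: Grid
    region_info: pd.DataFrame
    trails: list[list[tuple[float, float]]]
    parks: list
    metadata: dict


def generate_study_system(
    config: SynthConfig | None = None,
    species: list[SpeciesParams] | None = None,
) -> StudySystem:
    """Generate every input of the analysis from one config and seed.

    The candidate predictor stack deliberately includes elevation (which
    the screen should drop in favor of temperature) and shrubland (dropped
    in favor of herbaceous). Regions and incident counts are generated
    from the TRUE habitat union, so the analysis has to recover the
    association from its own predicted maps.
    """
    config = config or SynthConfig()
    species = species or default_species()
    (r_dem, r_clim, r_cov, r_pres, r_reg, r_trail) = _streams(config.seed, 6)

    dem = gen_dem(config, r_dem)
    temp, precip = gen_climate(dem, config, r_clim)
    covers = gen_covers(dem, config, r_cov, temperature=temp)
    slp = slope(dem)
    tpi_g = tpi(dem, TerrainParams(config.tpi_radius))

    names = [
        "elevation", "tpi", "slope", "bare", "herbaceous", "shrubland",
        "forest", "temperature", "precipitation",
    ]
    stack = PredictorStack(
        names,
        {
            "elevation": dem, "tpi": tpi_g, "slope": slp,
            "bare": covers["bare"], "herbaceous": covers["herbaceous"],
            "shrubland": covers["shrubland"], "forest": covers["forest"],
            "temperature": temp, "precipitation": precip,
        },
    )
    mask = Grid(dem.spec, np.ones(dem.spec.shape))

    suits: dict[str, Grid] = {}
    pres: dict[str, PointSet] = {}
    pres_streams = _streams(config.seed + 101, len(species))
    for sp, rs in zip(species, pres_streams):
        suits[sp.name] = true_suitability(stack, sp)
        n = config.presence_counts.get(sp.name, 100)
        pres[sp.name] = sample_presences(suits[sp.name], n, rs, species=sp.name)

    union_vals = np.zeros(dem.spec.shape)
    for sp in species:
        union_vals = np.maximum(union_vals, (suits[sp.name].values >= 0.5).astype(float))
    true_union = Grid(dem.spec, union_vals)

    regions, region_info = gen_regions_and_incidents(
        dem.spec, true_union, config, r_reg
    )
    trails, parks = gen_trails_and_parks(tpi_g, config, r_trail)

    metadata = {
        "config": asdict(config),
        "species": [asdict(sp) for sp in species],
        "seed": config.seed,
    }
    return StudySystem(
        config=config, stack=stack, mask=mask, species=species,
        suitability=suits, presences=pres, true_union=true_union,
        regions=regions, region_info=region_info,
        trails=trails, parks=parks, metadata=metadata,
    )


def write_study_system(system: StudySystem, out_dir) -> dict:
    """Write every generated input to disk and return a ready run config.

    Rasters go out as ASCII grids, vectors as GeoJSON, points and the
    region table as CSV, plus the answer-key metadata JSON and a
    ``run.yml`` the pipeline can consume directly.
    """
    import json
    from pathlib import Path

    import pandas as pd
    import yaml
    from shapely.geometry import LineString, box as shapely_box

    from .geodata import write_geojson, write_raster

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for name in system.stack.names:
        write_raster(system.stack[name], out / f"{name}.asc")
    write_raster(system.mask, out / "mask.asc")
    write_raster(system.regions, out / "regions_label.asc")

    frames = [
        pd.DataFrame({"species": sp, "x": pts.x, "y": pts.y, "label": pts.labels})
        for sp, pts in system.presences.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(out / "occurrences.csv", index=False)
    system.region_info.to_csv(out / "regions.csv", index=False)

    write_geojson(
        [({"id": i + 1}, LineString(t)) for i, t in enumerate(system.trails)],
        out / "trails.geojson",
    )
    write_geojson(
        [({"id": i + 1, "name": f"park_{i + 1}"}, p)
         for i, p in enumerate(system.parks)],
        out / "parks.geojson",
    )

    spec = system.regions.spec
    regions = []
    for rid in np.unique(system.regions.values).astype(int):
        if rid == 0:
            continue
        rows, cols = np.where(system.regions.values == rid)
        x0 = spec.origin_x + cols.min() * spec.cell_size
        x1 = spec.origin_x + (cols.max() + 1) * spec.cell_size
        y1 = spec.origin_y - rows.min() * spec.cell_size
        y0 = spec.origin_y - (rows.max() + 1) * spec.cell_size
        regions.append(({"id": int(rid), "name": f"region_{rid:02d}"},
                        shapely_box(x0, y0, x1, y1)))
    write_geojson(regions, out / "regions.geojson")

    (out / "metadata.json").write_text(json.dumps(system.metadata, indent=2))
    run_cfg = {
        "dem": str(out / "elevation.asc"),
        "mask": str(out / "mask.asc"),
        "occurrences": str(out / "occurrences.csv"),
        "species": [sp.name for sp in system.species],
        "layers": {
            n: str(out / f"{n}.asc")
            for n in system.stack.names if n not in ("elevation", "tpi", "slope")
        },
        "regions": str(out / "regions.geojson"),
        "incidents": str(out / "regions.csv"),
        "trails": str(out / "trails.geojson"),
        "parks": str(out / "parks.geojson"),
        "n_pseudo": system.config.n_pseudo_absences,
        # desk-scale fitting profile for the synthetic study system
        "n_trees": 250,
        "cv_folds": 5,
        "seed": system.config.seed,
    }
    (out / "run.yml").write_text(yaml.safe_dump(run_cfg, sort_keys=True))
    return run_cfg
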