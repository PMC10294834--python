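"""Downstream risk statistics built on the combined habitat map.

Per-species binary habitat maps are merged by cell-wise logical OR into a
single potential-habitat map ("at least one species present"). Everything
after binarization is raster-native: areas and proportions are cell
counts times the squared cell size, regional incidence is snakebite
patients per 10,000 residents, and the habitat-incidence association is
Spearman's rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import Grid, PredictorStack

__all__ = [
    "CorrelationResult",
    "union_maps",
    "incidence_per_10k",
    "regional_habitat_proportion",
    "spearman",
    "trail_overlap",
    "park_risk_ratio",
    "cover_composition",
    "build_region_table",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "t-approximation"


def union_maps(binary_maps: list[Grid]) -> Grid:
    """Cell-wise OR of binary habitat maps.

    A cell is 1 when at least one species map is 1, 0 when every valid map
    is 0, and nodata only where all inputs are nodata.
    """
    if not binary_maps:
        raise ValueError("need at least one binary map")
    spec = binary_maps[0].spec
    for g in binary_maps[1:]:
        if g.spec != spec:
            raise ValueError("binary maps must share an identical GridSpec")
    any_one = np.zeros(spec.shape, dtype=bool)
    any_valid = np.zeros(spec.shape, dtype=bool)
    for g in binary_maps:
        valid = g.valid()
        any_valid |= valid
        any_one |= valid & (g.values == 1)
    out = np.where(any_one, 1.0, 0.0)
    out = np.where(any_valid, out, spec.nodata)
    return Grid(spec, out)


def incidence_per_10k(count: float, population: float) -> float:
    """Snakebite incidents per 10,000 residents (unrounded).

    Reports round this to 2 decimals; the unrounded value is what
    correlation analysis consumes.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if count < 0:
        raise ValueError("incident count cannot be negative")
    return 1e4 * count / population


def regional_habitat_proportion(union: Grid, regions: Grid) -> pd.Series:
    """Habitat cells / total cells per region id; nodata cells excluded.

    Regions with no valid cells are reported as NaN.
    """
    if union.spec.shape != regions.spec.shape:
        raise ValueError("union and region grids must be aligned")
    valid = union.valid() & regions.valid() & (regions.values > 0)
    ids = np.unique(regions.values[regions.valid() & (regions.values > 0)]).astype(int)
    out = {}
    for rid in ids:
        m = valid & (regions.values == rid)
        total = int(m.sum())
        out[rid] = float((union.values[m] == 1).sum() / total) if total else np.nan
    return pd.Series(out, name="habitat_proportion")


def spearman(x, y, exact: bool = False) -> CorrelationResult:
    """Spearman rank correlation with a t-approximation p-value.

    rho is the Pearson correlation of mid-ranks; the two-sided p-value
    uses t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom. For
    n <= 10 an exact permutation p-value is available (``exact=True``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only offered for n <= 10")
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return CorrelationResult(rho, count / total, n, method="exact-permutation")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, min(max(p, np.finfo(float).tiny), 1.0), n)


def trail_overlap(union: Grid, trail_mask: Grid, zone_mask: Grid | None = None) -> float:
    """Fraction of (rasterized) trail cells lying on habitat, within a zone.

    Returns NaN with a warning when the zone holds no trail cells.
    """
    for g in (trail_mask, zone_mask):
        if g is not None and g.spec.shape != union.spec.shape:
            raise ValueError("grids must be aligned")
    zone = (
        np.ones(union.spec.shape, dtype=bool)
        if zone_mask is None
        else (zone_mask.valid() & (zone_mask.values > 0))
    )
    trail = trail_mask.valid() & (trail_mask.values == 1) & zone & union.valid()
    denom = int(trail.sum())
    if denom == 0:
        warnings.warn("no trail cells in the zone; overlap undefined")
        return float("nan")
    return float((union.values[trail] == 1).sum() / denom)


def park_risk_ratio(union: Grid, park_mask: Grid) -> float:
    """Habitat cells inside the park / park cells."""
    if union.spec.shape != park_mask.spec.shape:
        raise ValueError("grids must be aligned")
    park = park_mask.valid() & (park_mask.values > 0) & union.valid()
    total = int(park.sum())
    if total == 0:
        raise ValueError("park contains no valid cells")
    return float((union.values[park] == 1).sum() / total)


def cover_composition(union: Grid, cover_layers: PredictorStack) -> pd.Series:
    """Mean percent cover of each layer over habitat (union == 1) cells."""
    if cover_layers.spec.shape != union.spec.shape:
        raise ValueError("grids must be aligned")
    habitat = union.valid() & (union.values == 1)
    out = {}
    for name in cover_layers.names:
        layer = cover_layers[name]
        m = habitat & layer.valid()
        if not m.any():
            warnings.warn(f"no habitat cells with valid {name!r} cover")
            out[name] = float("nan")
        else:
            out[name] = float(layer.values[m].mean())
    return pd.Series(out, name="mean_percent_cover")


def build_region_table(
    union: Grid,
    regions: Grid,
    region_info: pd.DataFrame,
    trail_mask: Grid | None = None,
) -> pd.DataFrame:
    """Assemble the per-region summary table.

    ``region_info`` must carry columns id, name, population, snakebites.
    Output adds cell counts, area (km^2), incidence per 10,000 (unrounded
    plus a 2-dp reporting column), habitat proportion, and (when a trail
    mask is given) trail cell counts and trail-habitat overlap.
    """
    required = {"id", "name", "population", "snakebites"}
    if not required.issubset(region_info.columns):
        raise ValueError(f"region_info needs columns {sorted(required)}")
    props = regional_habitat_proportion(union, regions)
    rows = []
    for _, info in region_info.iterrows():
        rid = int(info["id"])
        in_region = regions.valid() & (regions.values == rid) & union.valid()
        n_cells = int(in_region.sum())
        rate = incidence_per_10k(float(info["snakebites"]), float(info["population"]))
        row = {
            "id": rid,
            "name": info["name"],
            "cell_count": n_cells,
            "area_km2": n_cells * union.spec.cell_area() / 1e6,
            "population": float(info["population"]),
            "snakebite_count": float(info["snakebites"]),
            "incidence_per_10k": rate,
            "incidence_per_10k_2dp": round(rate, 2),
            "habitat_proportion": props.get(rid, np.nan),
        }
        if trail_mask is not None:
            trail = (
                in_region & trail_mask.valid() & (trail_mask.values == 1)
            )
            row["trail_cell_count"] = int(trail.sum())
            row["trail_habitat_overlap"] = (
                float((union.values[trail] == 1).sum() / trail.sum())
                if trail.sum() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
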