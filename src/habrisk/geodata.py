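"""Raster/vector data model shared by every analysis stage.

Rasters follow the dominant GIS convention: the grid origin is the
top-left corner, row index increases southward, pixels are square and
half-open, and a point maps to the pixel ``floor((x - origin_x) / cell)``.
A single coordinate reference system is assumed throughout; ``crs_tag``
is carried as an opaque string and never interpreted.

On disk, single-band rasters use the ESRI ASCII grid format (``.asc``),
with the CRS tag in an optional ``.prj`` sidecar; vector data (trails,
regions, parks) travel as GeoJSON and point sets as CSV.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box, mapping, shape
from shapely import contains_xy

__all__ = [
    "GridSpec",
    "Grid",
    "PredictorStack",
    "PointSet",
    "read_raster",
    "write_raster",
    "resample_bilinear",
    "rasterize_lines",
    "rasterize_polygons",
    "read_points_csv",
    "write_points_csv",
    "read_geojson",
    "write_geojson",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a square-pixel raster grid.

    Pixel ``(r, c)`` covers the half-open square
    ``[origin_x + c*cell, origin_x + (c+1)*cell) x
    (origin_y - (r+1)*cell, origin_y - r*cell]`` where ``origin_x/y`` is
    the top-left corner of the grid.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 30.0
    crs_tag: str = "local"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map map-coordinates to (row, col) indices (floor rule)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def center_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (row, col) indices to pixel-center map coordinates."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def cell_area(self) -> float:
        return self.cell_size**2


@dataclass
class Grid:
    """A single-band raster: values plus grid geometry.

    ``values`` is an ``n_rows x n_cols`` float array; masked cells hold
    the spec's nodata sentinel. All non-nodata values are finite.
    """

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match spec {self.spec.shape}"
            )
        bad = ~np.isfinite(self.values) & ~self.mask_nodata()
        if bad.any():
            raise ValueError("grid contains non-finite values that are not nodata")

    def mask_nodata(self) -> np.ndarray:
        """Boolean mask, True where the cell is nodata."""
        with np.errstate(invalid="ignore"):
            return ~np.isfinite(self.values) | (self.values == self.spec.nodata)

    def valid(self) -> np.ndarray:
        return ~self.mask_nodata()

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.mask_nodata())

    def with_values(self, values: np.ndarray) -> "Grid":
        return Grid(self.spec, values)

    def area_of(self, predicate_mask: np.ndarray) -> float:
        """Area (map units squared) of the cells selected by the mask."""
        return int(np.count_nonzero(predicate_mask)) * self.spec.cell_area()


@dataclass
class PredictorStack:
    """Named, co-registered single-band rasters used as model covariates."""

    names: list[str]
    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("predictor names must be unique")
        missing = [n for n in self.names if n not in self.layers]
        if missing:
            raise ValueError(f"layers missing for: {missing}")
        specs = {self.layers[n].spec for n in self.names}
        if len(specs) > 1:
            raise ValueError("all layers in a stack must share an identical GridSpec")

    @property
    def spec(self) -> GridSpec:
        return self.layers[self.names[0]].spec

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: Sequence[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack has no layer(s) {missing}")
        return PredictorStack(list(names), {n: self.layers[n] for n in names})

    def valid_mask(self) -> np.ndarray:
        """Cells valid (non-nodata) in every layer."""
        m = np.ones(self.spec.shape, dtype=bool)
        for n in self.names:
            m &= self.layers[n].valid()
        return m

    def extract(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        """Sample every layer at the given map coordinates (nearest cell)."""
        row, col = self.spec.cell_of(np.asarray(x), np.asarray(y))
        inside = (
            (row >= 0) & (row < self.spec.n_rows) & (col >= 0) & (col < self.spec.n_cols)
        )
        if not inside.all():
            raise ValueError("points fall outside the stack extent")
        data = {n: self.layers[n].values[row, col] for n in self.names}
        return pd.DataFrame(data)

    def to_matrix(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Flatten valid cells to a (n_cells, n_vars) matrix.

        Returns the matrix and the flat indices of the cells it came from.
        """
        m = self.valid_mask() if mask is None else (mask & self.valid_mask())
        idx = np.flatnonzero(m.ravel())
        cols = [self.layers[n].values.ravel()[idx] for n in self.names]
        return np.column_stack(cols), idx


@dataclass
class PointSet:
    """Point observations for one species with presence/absence labels."""

    species: str
    coords: np.ndarray  # (n, 2) map coordinates
    labels: np.ndarray  # 1 = presence, 0 = pseudo-absence

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.coords) != len(self.labels):
            raise ValueError("coords and labels length mismatch")
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    def concat(self, other: "PointSet") -> "PointSet":
        if other.species != self.species:
            raise ValueError("cannot concatenate point sets of different species")
        return PointSet(
            self.species,
            np.vstack([self.coords, other.coords]),
            np.concatenate([self.labels, other.labels]),
        )


# ---------------------------------------------------------------------------
# Raster I/O — ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_raster(grid: Grid, path: str | Path) -> None:
    """Write a Grid as an ESRI ASCII grid (.asc) with a .prj CRS sidecar.

    Values are written with 17 significant digits so the write->read
    round trip is bit-exact for double precision data.
    """
    path = Path(path)
    s = grid.spec
    yll = s.origin_y - s.n_rows * s.cell_size
    header = (
        f"ncols {s.n_cols}\n"
        f"nrows {s.n_rows}\n"
        f"xllcorner {s.origin_x!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {s.cell_size!r}\n"
        f"NODATA_value {s.nodata!r}\n"
    )
    vals = np.where(grid.mask_nodata(), s.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")
    path.with_suffix(".prj").write_text(s.crs_tag + "\n")


def read_raster(path: str | Path) -> Grid:
    """Read a single-band ESRI ASCII grid raster."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "dx", "dy", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    if "dx" in header or "dy" in header:
        raise ValueError("non-square pixels (dx/dy headers) are not supported")
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid: missing {key} in {path}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    values = np.loadtxt(path, skiprows=n_header, ndmin=2)
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"raster body has {values.size} values, expected {n_rows * n_cols}"
        )
    values = values.reshape(n_rows, n_cols)
    prj = path.with_suffix(".prj")
    crs_tag = prj.read_text().strip() if prj.exists() else "local"
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        crs_tag=crs_tag,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )
    return Grid(spec, values)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_bilinear(src: Grid, target: GridSpec) -> Grid:
    """Resample a continuous raster onto a new grid by bilinear interpolation.

    Each target cell takes the bilinear interpolation of the four source
    cell centers surrounding its own center. Within half a source cell of
    the border, the border value is replicated. Target cells whose centers
    fall outside the source extent become nodata; source nodata spreads to
    any target cell whose interpolation stencil touches it.
    """
    s = src.spec
    xmin, ymin, xmax, ymax = s.extent
    rows = np.arange(target.n_rows)
    cols = np.arange(target.n_cols)
    cgrid, rgrid = np.meshgrid(cols, rows)
    tx, ty = target.center_of(rgrid, cgrid)

    outside = ~s.contains(tx, ty)

    # fractional index of the target center in source cell-center space
    gx = (tx - s.origin_x) / s.cell_size - 0.5
    gy = (s.origin_y - ty) / s.cell_size - 0.5
    gx = np.clip(gx, 0.0, s.n_cols - 1.0)
    gy = np.clip(gy, 0.0, s.n_rows - 1.0)

    x0 = np.floor(gx).astype(int)
    y0 = np.floor(gy).astype(int)
    x1 = np.minimum(x0 + 1, s.n_cols - 1)
    y1 = np.minimum(y0 + 1, s.n_rows - 1)
    fx = gx - x0
    fy = gy - y0

    v = src.values
    nd = src.mask_nodata()
    out = (
        v[y0, x0] * (1 - fx) * (1 - fy)
        + v[y0, x1] * fx * (1 - fy)
        + v[y1, x0] * (1 - fx) * fy
        + v[y1, x1] * fx * fy
    )
    touched_nd = nd[y0, x0] | nd[y0, x1] | nd[y1, x0] | nd[y1, x1]
    out = np.where(outside | touched_nd, target.nodata, out)
    return Grid(target, out)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_lines(
    polylines: Iterable[Sequence[tuple[float, float]]], spec: GridSpec
) -> Grid:
    """Burn polylines onto a binary grid, all-touched.

    A cell becomes 1 if any segment intersects the cell's square (including
    corner clips); an empty polyline set yields an all-zero grid. The result
    is independent of vertex order within each polyline.
    """
    out = np.zeros(spec.shape, dtype=float)
    cs = spec.cell_size
    for line in polylines:
        pts = [(float(x), float(y)) for x, y in line]
        if not pts:
            continue
        geom = Point(pts[0]) if len(pts) == 1 or len(set(pts)) == 1 else LineString(pts)
        # iterate segments to keep the candidate window small
        segments = (
            [geom]
            if geom.geom_type == "Point"
            else [LineString(pts[i : i + 2]) for i in range(len(pts) - 1)]
        )
        for seg in segments:
            bxmin, bymin, bxmax, bymax = seg.bounds
            r0, c0 = spec.cell_of(bxmin, bymax)
            r1, c1 = spec.cell_of(bxmax, bymin)
            r0 = max(int(r0), 0)
            c0 = max(int(c0), 0)
            r1 = min(int(r1), spec.n_rows - 1)
            c1 = min(int(c1), spec.n_cols - 1)
            for r in range(r0, r1 + 1):
                ytop = spec.origin_y - r * cs
                for c in range(c0, c1 + 1):
                    if out[r, c]:
                        continue
                    xleft = spec.origin_x + c * cs
                    cell = box(xleft, ytop - cs, xleft + cs, ytop)
                    if seg.intersects(cell):
                        out[r, c] = 1.0
    return Grid(replace(spec, nodata=DEFAULT_NODATA), out)


def rasterize_polygons(
    polygons_with_ids: Iterable[tuple[int, "object"]], spec: GridSpec
) -> Grid:
    """Label cells by the polygon containing their center; 0 = background.

    ``polygons_with_ids`` yields ``(id, polygon)`` with positive integer
    ids; shapely geometries or GeoJSON-like mappings are accepted. Where
    polygons overlap the lowest id wins and a warning is issued.
    """
    out = np.zeros(spec.shape, dtype=float)
    rows = np.arange(spec.n_rows)
    cols = np.arange(spec.n_cols)
    cgrid, rgrid = np.meshgrid(cols, rows)
    cx, cy = spec.center_of(rgrid, cgrid)

    items = []
    for pid, poly in polygons_with_ids:
        pid = int(pid)
        if pid <= 0:
            raise ValueError("polygon ids must be positive integers (0 = background)")
        geom = poly if hasattr(poly, "geom_type") else shape(poly)
        items.append((pid, geom))

    overlap_warned = False
    # highest id first so that lower ids overwrite on ties
    for pid, geom in sorted(items, key=lambda t: -t[0]):
        inside = contains_xy(geom, cx.ravel(), cy.ravel()).reshape(spec.shape)
        clash = inside & (out > 0) & (out != pid)
        if clash.any() and not overlap_warned:
            warnings.warn(
                "overlapping polygons during rasterization; lowest id wins",
                stacklevel=2,
            )
            overlap_warned = True
        out[inside] = pid
    return Grid(replace(spec, nodata=DEFAULT_NODATA), out)


# ---------------------------------------------------------------------------
# Vector / point I/O
# ---------------------------------------------------------------------------

def write_points_csv(points: PointSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "species": points.species,
            "x": points.coords[:, 0],
            "y": points.coords[:, 1],
            "label": points.labels,
        }
    )
    df.to_csv(path, index=False)


def read_points_csv(path: str | Path, species: str | None = None) -> PointSet:
    df = pd.read_csv(path)
    required = {"species", "x", "y", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"point CSV must have columns {sorted(required)}")
    if species is not None:
        df = df[df["species"] == species]
        name = species
    else:
        uniq = df["species"].unique()
        if len(uniq) != 1:
            raise ValueError("point CSV holds several species; pass species=...")
        name = uniq[0]
    return PointSet(name, df[["x", "y"]].to_numpy(float), df["label"].to_numpy(int))


def write_geojson(
    features: Iterable[tuple[Mapping, "object"]], path: str | Path
) -> None:
    """Write (properties, geometry) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": dict(props),
                "geometry": mapping(geom) if hasattr(geom, "geom_type") else geom,
            }
            for props, geom in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[tuple[dict, "object"]]:
    """Read a GeoJSON FeatureCollection as (properties, shapely geometry) pairs."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    return [
        (feat.get("properties") or {}, shape(feat["geometry"]))
        for feat in doc["features"]
    ]
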