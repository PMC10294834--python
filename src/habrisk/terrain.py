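"""Terrain derivatives: slope and topographic position index (TPI).

Both are computed from a DEM whose elevations share linear units with the
grid's cell size. Slope uses the Horn 3x3 finite-difference operator (the
common GIS default) with replicated borders; TPI subtracts the mean
elevation of a square neighborhood (center excluded) so that valleys come
out negative and ridges positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .geodata import Grid

__all__ = ["TerrainParams", "slope", "tpi"]


@dataclass(frozen=True)
class TerrainParams:
    """Parameters for terrain derivatives.

    tpi_radius is the neighborhood half-width in cells: radius 1 means a
    3x3 window. Slope is always reported in degrees.
    """

    tpi_radius: int = 1

    def __post_init__(self) -> None:
        if self.tpi_radius < 1:
            raise ValueError("tpi_radius must be >= 1")


def _prepare_dem(dem: Grid) -> tuple[np.ndarray, np.ndarray]:
    if dem.spec.n_rows < 2 or dem.spec.n_cols < 2:
        raise ValueError("terrain derivatives need at least a 2x2 DEM")
    nd = dem.mask_nodata()
    z = np.where(nd, np.nan, dem.values)
    return z, nd


def slope(dem: Grid) -> Grid:
    """Slope in degrees via the Horn 3x3 operator.

    Border cells use replicated edges. Nodata cells stay nodata; a nodata
    neighbor inside the 3x3 window is substituted with the center elevation
    (local-flat assumption) so slope does not bleed across mask borders.
    """
    z, nd = _prepare_dem(dem)
    cs = dem.spec.cell_size
    zp = np.pad(z, 1, mode="edge")
    center = zp[1:-1, 1:-1]

    def w(dr: int, dc: int) -> np.ndarray:
        win = zp[1 + dr : zp.shape[0] - 1 + dr, 1 + dc : zp.shape[1] - 1 + dc]
        return np.where(np.isnan(win), center, win)

    a, b, c = w(-1, -1), w(-1, 0), w(-1, 1)
    d, f = w(0, -1), w(0, 1)
    g, h, i = w(1, -1), w(1, 0), w(1, 1)
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out = np.where(nd, dem.spec.nodata, deg)
    return Grid(dem.spec, out)


def tpi(dem: Grid, params: TerrainParams = TerrainParams()) -> Grid:
    """Topographic position index over a (2r+1)^2 square neighborhood.

    TPI(cell) = elevation(cell) − mean(elevation of neighbors), center
    excluded. Edge cells use only the neighbors that exist; nodata cells are
    excluded from every mean and stay nodata in the output.
    """
    r = params.tpi_radius
    if 2 * r + 1 > min(dem.spec.n_rows, dem.spec.n_cols):
        raise ValueError(
            f"tpi_radius {r} needs a window larger than the {dem.spec.shape} grid"
        )
    z, nd = _prepare_dem(dem)
    filled = np.where(nd, 0.0, z)
    ones = np.where(nd, 0.0, 1.0)
    k = np.ones((2 * r + 1, 2 * r + 1))
    # constant-0 padding: sums/counts automatically cover only available cells
    s = convolve(filled, k, mode="constant", cval=0.0)
    n = convolve(ones, k, mode="constant", cval=0.0)
    s_nb = s - filled
    n_nb = n - ones
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nb = s_nb / n_nb
    val = z - mean_nb
    val = np.where(n_nb == 0, 0.0, val)  # isolated cell: no neighbors, TPI 0
    out = np.where(nd, dem.spec.nodata, val)
    return Grid(dem.spec, out)
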