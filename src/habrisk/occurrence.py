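"""Occurrence preparation: one-presence-per-pixel thinning and
pseudo-absence (background) generation.

Survey presence records often pile up several points inside one raster
cell; keeping one per cell removes the grossest duplication bias before
model fitting. Pseudo-absences stand in for true absences: random cell
centers drawn uniformly from the analyzable study area, never inside a
cell already holding a presence point.
"""

from __future__ import annotations

import numpy as np

from .geodata import Grid, GridSpec, PointSet

__all__ = ["thin_to_pixel", "sample_pseudo_absences"]


def thin_to_pixel(points: PointSet, spec: GridSpec, seed: int) -> PointSet:
    """Keep at most one presence point per raster pixel.

    When several points share a pixel, one survives, chosen uniformly at
    random with the given seed (record order carries no meaning). Output is
    deterministic: points are returned in row-major pixel order.
    """
    if len(points) and not (points.labels == 1).all():
        raise ValueError("thinning applies to presence points only")
    if len(points) == 0:
        return PointSet(points.species, np.empty((0, 2)), np.empty(0, dtype=int))
    row, col = spec.cell_of(points.x, points.y)
    pix = row * spec.n_cols + col
    rng = np.random.default_rng(seed)
    keep: dict[int, int] = {}
    # reservoir-sample one record index per occupied pixel
    counts: dict[int, int] = {}
    for i, p in enumerate(pix):
        p = int(p)
        counts[p] = counts.get(p, 0) + 1
        if rng.random() < 1.0 / counts[p]:
            keep[p] = i
    order = sorted(keep)
    idx = [keep[p] for p in order]
    return PointSet(points.species, points.coords[idx], points.labels[idx])


def sample_pseudo_absences(
    mask: Grid, n: int, seed: int, exclude: PointSet | None = None
) -> PointSet:
    """Draw n pseudo-absence points uniformly from the study mask.

    Cells are drawn without replacement from mask==1 cells that do not
    contain any excluded presence point; each point sits at its cell
    center and carries label 0. Reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = (mask.values == 1) & mask.valid()
    species = "background"
    if exclude is not None and len(exclude):
        species = exclude.species
        row, col = mask.spec.cell_of(exclude.x, exclude.y)
        inside = (
            (row >= 0)
            & (row < mask.spec.n_rows)
            & (col >= 0)
            & (col < mask.spec.n_cols)
        )
        eligible[row[inside], col[inside]] = False
    flat = np.flatnonzero(eligible.ravel())
    if len(flat) < n:
        raise ValueError(
            f"cannot draw {n} pseudo-absences: only {len(flat)} eligible cells "
            f"({n - len(flat)} short)"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    row, col = np.divmod(chosen, mask.spec.n_cols)
    x, y = mask.spec.center_of(row, col)
    return PointSet(species, np.column_stack([x, y]), np.zeros(n, dtype=int))
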