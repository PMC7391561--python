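"""Least-accumulative-cost distance from a source line over a cost raster.

Reproduces the classic GIS cost-distance semantics: movement between
8-connected cell centers costs the mean of the two cells' per-cell
impedance times the planimetric move length (cell size for orthogonal
moves, sqrt(2) times that for diagonals).  The accumulated surface is the
exact shortest-path (Dijkstra) optimum from the rasterized source cells.

Elevation serves directly as the impedance, so low-elevation corridors
(valley bottoms) act as cheap colonization pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from refugeo.datatypes import Raster, SourceLine
from refugeo.popgen import EARTH_RADIUS_KM

log = logging.getLogger("refugeo")

KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0  # 111.195 km


@dataclass
class CostSurface:
    """Accumulated cost raster plus the binary source mask."""

    raster: Raster
    source_mask: np.ndarray


def rasterize_source(line: SourceLine, template: Raster) -> Raster:
    """Burn a polyline into a binary raster on the template's geometry.

    A cell is a source cell if its center lies within half a cell size of
    the line or if the line passes through the cell (supercover), which
    guarantees a gap-free chain of cells along the line.
    """
    geom = shapely.LineString(line.vertices)
    lon2d, lat2d = template.centers()
    pts = shapely.points(lon2d.ravel(), lat2d.ravel())
    near = shapely.distance(pts, geom) < template.cellsize / 2.0
    mask = near.reshape(template.values.shape)
    # supercover: sample the line densely and mark traversed cells
    step = template.cellsize / 5.0
    n_samples = max(int(np.ceil(geom.length / step)) + 1, 2)
    for frac in np.linspace(0.0, 1.0, n_samples):
        p = geom.interpolate(frac, normalized=True)
        try:
            row, col = template.rowcol(p.x, p.y)
        except ValueError:
            continue
        mask[row, col] = True
    if not mask.any():
        raise ValueError("source line does not intersect the raster extent")
    return template.copy_with(mask.astype(float))


def _move_lengths(raster: Raster, geographic: bool) -> tuple[np.ndarray, float]:
    """Per-row E-W move length and the N-S move length (raster units or km)."""
    if not geographic:
        return np.full(raster.n_rows, raster.cellsize), raster.cellsize
    _, lat2d = raster.centers()
    row_lat = lat2d[:, 0]
    dx = KM_PER_DEGREE * np.cos(np.radians(row_lat)) * raster.cellsize
    dy = KM_PER_DEGREE * raster.cellsize
    return dx, dy


def accumulate_cost(
    cost: Raster, sources: Raster, geographic: bool = False, min_cost: float = 1.0
) -> CostSurface:
    """Exact multi-source Dijkstra accumulated-cost surface.

    ``cost`` holds per-cell impedance (elevation in the colonization
    application); cells at or below zero are floored at ``min_cost`` to
    keep edge weights positive.  ``sources`` is a binary raster on the
    same geometry.  In ``geographic`` mode move lengths are km, with the
    E-W dimension scaled by cos(latitude of the cell row).

    Returns a surface that is 0 exactly on source cells, finite on every
    cell reachable through valid (non-nodata) cells, and nodata elsewhere.
    """
    if cost.values.shape != sources.values.shape:
        raise ValueError("cost and source rasters must share geometry")
    valid = cost.mask()
    if not valid.any():
        raise ValueError("cost raster is entirely nodata")
    src = (sources.values == 1) & valid
    if not src.any():
        raise ValueError("no source cell on a valid cost cell")
    nrows, ncols = cost.values.shape
    c = np.where(valid, np.maximum(cost.values, min_cost), np.nan)
    dx, dy = _move_lengths(cost, geographic)

    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    rows_i, cols_j, weights = [], [], []

    def add_edges(dr: int, dc: int) -> None:
        a = idx[max(0, -dr): nrows - max(0, dr), max(0, -dc): ncols - max(0, dc)]
        b = idx[max(0, dr): nrows + min(0, dr), max(0, dc): ncols + min(0, dc)]
        ca = c.ravel()[a.ravel()]
        cb = c.ravel()[b.ravel()]
        ok = np.isfinite(ca) & np.isfinite(cb)
        if dr == 0:
            length = dx[a.ravel() // ncols]
        elif dc == 0:
            length = np.full(a.size, dy)
        else:  # diagonal: E-W component at the mean latitude of the two rows
            dxa = dx[a.ravel() // ncols]
            dxb = dx[b.ravel() // ncols]
            length = np.hypot((dxa + dxb) / 2.0, dy)
        w = (ca + cb) / 2.0 * length
        rows_i.append(a.ravel()[ok])
        cols_j.append(b.ravel()[ok])
        weights.append(w[ok])

    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        add_edges(dr, dc)
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    w = np.concatenate(weights)
    n = nrows * ncols
    graph = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    source_idx = np.flatnonzero(src.ravel())
    dist = dijkstra(graph, directed=False, indices=source_idx, min_only=True)
    out = dist.reshape(nrows, ncols)
    out = np.where(np.isfinite(out) & valid, out, cost.nodata)
    return CostSurface(raster=cost.copy_with(out), source_mask=src)


def extract_cost(surface: CostSurface, pops: pd.DataFrame) -> pd.DataFrame:
    """Attach each population's accumulated cost as ``cost_distance``.

    Populations outside the raster extent raise an error listing their
    ids; populations on nodata (unreachable) cells are flagged NaN with a
    warning and excluded from downstream history predictors by listwise
    deletion.
    """
    raster = surface.raster
    values = []
    outside = []
    on_nodata = []
    for _, row in pops.iterrows():
        try:
            r, col = raster.rowcol(row["lon"], row["lat"])
        except ValueError:
            outside.append(row["pop_id"])
            values.append(np.nan)
            continue
        v = raster.values[r, col]
        if v == raster.nodata or not np.isfinite(v):
            on_nodata.append(row["pop_id"])
            values.append(np.nan)
        else:
            values.append(float(v))
    if outside:
        raise ValueError(f"population(s) outside raster extent: {outside}")
    if on_nodata:
        log.warning("population(s) on nodata cells, cost_distance flagged missing: %s", on_nodata)
    out = pops.copy()
    out["cost_distance"] = values
    return out
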