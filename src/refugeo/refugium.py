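"""Grid-correlation inference of the postglacial colonization source.

Under serial founder effects, genetic diversity and rarity decline away
from the colonization source.  The study area is divided into a regular
lon/lat grid; for every cell, each genetic index is Spearman-correlated
with the distance from the cell centroid to every genotyped population.
Cells at or near the source show strongly negative correlations.  Cells
are ranked per index (rank 1 = most negative = most source-like), the
four rankings are averaged into a combined rank, and the sign of the
Spearman correlation between combined rank and latitude gives the
colonization direction (positive: source at the southern margin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from refugeo.errors import GridError
from refugeo.popgen import haversine_km

log = logging.getLogger("refugeo")


@dataclass(frozen=True)
class AnalysisGrid:
    """Regular lon/lat grid; cells are row-major with row 0 at the south."""

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    cell_size: float
    n_rows: int
    n_cols: int

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays (lon, lat) of all cell centroids, row-major."""
        lon = self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.lat_min + (np.arange(self.n_rows) + 0.5) * self.cell_size
        lon2d, lat2d = np.meshgrid(lon, lat)
        return lon2d.ravel(), lat2d.ravel()

    def cell_of(self, lon: float, lat: float) -> int:
        """Flat index of the cell containing a point."""
        col = int(np.floor((lon - self.lon_min) / self.cell_size))
        row = int(np.floor((lat - self.lat_min) / self.cell_size))
        col = min(max(col, 0), self.n_cols - 1)
        row = min(max(row, 0), self.n_rows - 1)
        return row * self.n_cols + col


@dataclass
class GridSurface:
    """One value per grid cell (a correlation coefficient or a rank)."""

    grid: AnalysisGrid
    values: np.ndarray  # flat, row-major; NaN = undefined
    index_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError("values must be flat with one entry per cell")


@dataclass
class DirectionResult:
    """Outcome of the combined-rank vs latitude direction test."""

    rho: float
    p: float
    inferred_source: str  # "north" or "south"
    variant: str = "cell"


def build_grid(
    lon_min: float, lat_min: float, lon_max: float, lat_max: float, cell_size: float
) -> AnalysisGrid:
    """Build a regular analysis grid; bounds must be integral multiples of
    the cell size (within 1e-9 cells) or an error suggests snapped bounds."""
    if lon_max <= lon_min or lat_max <= lat_min:
        raise GridError("bounds must satisfy lon_max > lon_min and lat_max > lat_min")
    if cell_size <= 0:
        raise GridError("cell_size must be positive")
    out = []
    for span, name in (((lon_max - lon_min), "lon"), ((lat_max - lat_min), "lat")):
        ratio = span / cell_size
        n = round(ratio)
        if n < 1:
            raise GridError(f"cell_size larger than the {name} extent")
        if abs(ratio - n) > 1e-9:
            snapped = n * cell_size
            raise GridError(
                f"{name} span {span} is not an integral number of cells; "
                f"try a span of {snapped}"
            )
        out.append(n)
    n_cols, n_rows = out
    return AnalysisGrid(
        lon_min=lon_min,
        lat_min=lat_min,
        lon_max=lon_max,
        lat_max=lat_max,
        cell_size=cell_size,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def correlation_surface(
    grid: AnalysisGrid,
    pops: pd.DataFrame,
    index_values: pd.Series | np.ndarray,
    index_name: str = "",
    metric: str = "haversine",
) -> GridSurface:
    """Spearman correlation of centroid-to-population distance with a
    genetic index, for every grid cell.

    Populations with undefined (NaN) index values are excluded.  Distances
    use the haversine great-circle formula by default; ``metric="planar"``
    uses plain Euclidean degrees (legacy mode; ranks are usually identical
    at this spatial extent).
    """
    vals = np.asarray(index_values, dtype=float)
    keep = np.isfinite(vals)
    if keep.sum() < 3:
        raise ValueError("need at least 3 populations with defined index values")
    lon = pops["lon"].to_numpy(float)[keep]
    lat = pops["lat"].to_numpy(float)[keep]
    vals = vals[keep]
    if np.ptp(vals) == 0:
        log.warning("index %r is constant; all cells undefined", index_name)
        return GridSurface(grid=grid, values=np.full(grid.n_cells, np.nan), index_name=index_name)
    clon, clat = grid.centroids()
    if metric == "haversine":
        dist = haversine_km(clon[:, None], clat[:, None], lon[None, :], lat[None, :])
    elif metric == "planar":
        dist = np.hypot(clon[:, None] - lon[None, :], clat[:, None] - lat[None, :])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # Spearman = Pearson on average ranks; vectorized across cells.
    rv = stats.rankdata(vals)
    rd = stats.rankdata(dist, axis=1)
    rv_c = rv - rv.mean()
    rd_c = rd - rd.mean(axis=1, keepdims=True)
    denom = np.sqrt((rd_c**2).sum(axis=1) * (rv_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rd_c @ rv_c) / denom
    return GridSurface(grid=grid, values=rho, index_name=index_name)


def rank_cells(surface: GridSurface) -> GridSurface:
    """Rank cells ascending by correlation coefficient.

    Rank 1 = most negative coefficient = most source-like.  Ties receive
    average ranks; undefined cells stay NaN.
    """
    vals = surface.values
    defined = np.isfinite(vals)
    if not defined.any():
        raise ValueError("all cells undefined; cannot rank")
    ranks = np.full_like(vals, np.nan)
    ranks[defined] = stats.rankdata(vals[defined])
    return GridSurface(grid=surface.grid, values=ranks, index_name=f"rank({surface.index_name})")


def combine_ranks(surfaces: list[GridSurface]) -> GridSurface:
    """Average per-cell ranks across indices into the combined ranking."""
    if len(surfaces) < 2:
        raise ValueError("need at least 2 rank surfaces to combine")
    grid = surfaces[0].grid
    for s in surfaces[1:]:
        if s.grid != grid:
            raise ValueError("rank surfaces are on different grids")
    stacked = np.vstack([s.values for s in surfaces])
    combined = stacked.mean(axis=0)
    return GridSurface(grid=grid, values=combined, index_name="combined_rank")


def direction_test(
    combined: GridSurface,
    pops: pd.DataFrame | None = None,
    variant: str = "cell",
    n_perm: int | None = None,
    seed: int | None = None,
) -> DirectionResult:
    """Correlate the combined rank with latitude to infer the direction.

    ``variant="cell"`` uses every defined cell's centroid latitude;
    ``variant="population"`` uses each population's latitude against its
    containing cell's combined rank.  Positive Spearman rho means low
    (source-like) ranks sit at low latitudes: the source is the southern
    margin; negative rho points north.  The p value is asymptotic unless
    ``n_perm`` is given.
    """
    if variant == "cell":
        _, clat = combined.grid.centroids()
        lats = clat
        vals = combined.values
    elif variant == "population":
        if pops is None:
            raise ValueError("population variant needs the population table")
        cells = [combined.grid.cell_of(lo, la) for lo, la in zip(pops["lon"], pops["lat"])]
        vals = combined.values[cells]
        lats = pops["lat"].to_numpy(float)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    defined = np.isfinite(vals)
    if defined.sum() < 3:
        raise ValueError("need at least 3 defined cells for the direction test")
    vals, lats = vals[defined], lats[defined]
    rho, p = stats.spearmanr(vals, lats)
    if n_perm:
        rng = np.random.default_rng(seed)
        count = sum(
            abs(stats.spearmanr(vals, rng.permutation(lats)).statistic) >= abs(rho)
            for _ in range(n_perm)
        )
        p = (count + 1.0) / (n_perm + 1.0)
    source = "south" if rho > 0 else "north"
    return DirectionResult(rho=float(rho), p=float(p), inferred_source=source, variant=variant)


def surface_to_raster(surface: GridSurface):
    """Convert a GridSurface to a Raster (row 0 = north) for .asc export."""
    from refugeo.datatypes import Raster

    grid = surface.grid
    vals = surface.values.reshape(grid.n_rows, grid.n_cols)[::-1]
    return Raster(
        values=np.where(np.isfinite(vals), vals, -9999.0),
        xll=grid.lon_min,
        yll=grid.lat_min,
        cellsize=grid.cell_size,
        nodata=-9999.0,
    )
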