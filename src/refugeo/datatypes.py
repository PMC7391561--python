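"""Core data containers shared by all analysis stages.

Population tables travel as :class:`pandas.DataFrame` objects validated by
:func:`refugeo.io.read_population_table`; the bespoke containers below hold
the structures pandas does not model naturally (binary marker matrices,
gapped alignments, rasters, distance matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from refugeo.errors import FormatError

#: Columns a population table must provide.  ``cost_distance`` is appended
#: later by :func:`refugeo.costdist.extract_cost`.
POPULATION_COLUMNS = (
    "pop_id",
    "lon",
    "lat",
    "present_4x",
    "present_5x",
    "present_7x",
    "present_8x",
    "elevation",
    "inclination",
    "aspect",
    "land_use",
    "ndvi",
    "bio04",
    "bio12",
    "bio15",
)

PRESENCE_COLUMNS = ("present_4x", "present_5x", "present_7x", "present_8x")

#: Ecological predictors, in screening order.
ECO_COLUMNS = (
    "elevation",
    "inclination",
    "aspect",
    "land_use",
    "ndvi",
    "bio04",
    "bio12",
    "bio15",
)

APO_COLUMNS = ("present_5x", "present_7x", "present_8x")


@dataclass
class AFLPMatrix:
    """Individuals x loci binary band matrix for dominant markers.

    Parameters
    ----------
    individuals
        Ordered individual identifiers (rows of ``bands``).
    pop_of
        Mapping from individual id to population id.
    bands
        ``(n_individuals, n_loci)`` array with entries in {0, 1}.
    """

    individuals: list[str]
    pop_of: dict[str, str]
    bands: np.ndarray

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 2:
            raise ValueError("bands must be a 2-D matrix")
        if len(self.individuals) != self.bands.shape[0]:
            raise ValueError("individuals and bands row count disagree")
        if not np.isin(self.bands, (0, 1)).all():
            raise ValueError("band entries must be 0 or 1")
        missing = [i for i in self.individuals if i not in self.pop_of]
        if missing:
            raise ValueError(f"individuals without a population: {missing[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.bands.shape[0]

    @property
    def n_loci(self) -> int:
        return self.bands.shape[1]

    def populations(self) -> dict[str, np.ndarray]:
        """Group band rows by population, preserving individual order."""
        groups: dict[str, list[int]] = {}
        for row, ind in enumerate(self.individuals):
            groups.setdefault(self.pop_of[ind], []).append(row)
        return {pop: self.bands[rows] for pop, rows in groups.items()}


@dataclass
class HaplotypeData:
    """Aligned plastid sequences with coded indel characters.

    ``indel_characters`` holds one binary column per distinct gap event
    (identical start/end across sequences); it is appended to the
    nucleotide alignment when computing nucleotide diversity so that
    indels count as single polymorphic sites.
    """

    individuals: list[str]
    pop_of: dict[str, str]
    alignment: list[str]
    indel_characters: np.ndarray = field(default=None)  # type: ignore[assignment]
    haplotype_id: dict[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.individuals) != len(self.alignment):
            raise ValueError("individuals and alignment length disagree")
        lengths = {len(s) for s in self.alignment}
        if len(lengths) > 1:
            raise FormatError(f"alignment has unequal sequence lengths: {sorted(lengths)}")
        if self.indel_characters is None:
            from refugeo.io import code_indels

            self.indel_characters = code_indels(self.alignment)
        self.indel_characters = np.asarray(self.indel_characters)
        if self.indel_characters.size and self.indel_characters.shape[0] != len(
            self.individuals
        ):
            raise ValueError("indel_characters rows must match individuals")
        if self.haplotype_id is None:
            self.haplotype_id = self._assign_haplotypes()

    def _assign_haplotypes(self) -> dict[str, str]:
        seen: dict[tuple, str] = {}
        out: dict[str, str] = {}
        for row, ind in enumerate(self.individuals):
            indels = (
                tuple(self.indel_characters[row]) if self.indel_characters.size else ()
            )
            key = (self.alignment[row], indels)
            if key not in seen:
                seen[key] = f"H{len(seen) + 1}"
            out[ind] = seen[key]
        return out

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def populations(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = {}
        for row, ind in enumerate(self.individuals):
            groups.setdefault(self.pop_of[ind], []).append(row)
        return groups


@dataclass
class Raster:
    """Regular grid of values in the ESRI ASCII-grid convention.

    ``values[0, :]`` is the **northernmost** row (file order); ``origin``
    is the lower-left corner ``(xll, yll)``.  ``cellsize`` is in the
    declared unit (degrees by default, metres for projected inputs).
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center; row 0 is the northernmost row."""
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.n_rows - row - 0.5) * self.cellsize
        return lon, lat

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of cell-center lon and lat, shaped like ``values``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.xll + (cols + 0.5) * self.cellsize
        lat = self.yll + (self.n_rows - rows - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def rowcol(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing a point; raises if outside the extent."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(
            values=np.asarray(values, dtype=float),
            xll=self.xll,
            yll=self.yll,
            cellsize=self.cellsize,
            nodata=self.nodata,
        )


@dataclass
class SourceLine:
    """Polyline marking the colonization source (e.g. an LGM ice margin)."""

    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("a source line needs at least 2 vertices")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled axes."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy 'condensed' (row-major) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]
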