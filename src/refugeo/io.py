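"""Readers, writers and predictor preparation.

Standard formats handled here: population CSV, FASTA (via Biopython),
ESRI ASCII grid, GeoJSON LineString.  Predictor preparation follows the
regression conventions of the analysis: continuous covariates are scaled
to zero mean and unit sample variance, annual precipitation (bio12) is
cube-root transformed first, and the binary land-use indicator is left
unscaled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from refugeo.datatypes import (
    APO_COLUMNS,
    ECO_COLUMNS,
    POPULATION_COLUMNS,
    PRESENCE_COLUMNS,
    Raster,
    SourceLine,
)
from refugeo.errors import FormatError

log = logging.getLogger("refugeo")


# ---------------------------------------------------------------------------
# population table
# ---------------------------------------------------------------------------

def read_population_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a population table CSV.

    Required columns are listed in
    :data:`refugeo.datatypes.POPULATION_COLUMNS`; ``cost_distance`` is
    optional (it is computed by the cost-distance stage).  Rows with
    missing coordinates and non-binary presence flags are rejected with
    row-numbered messages (row numbers are 1-based data rows, header
    excluded).
    """
    df = pd.read_csv(path)
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"population table missing required column(s): {missing}")
    bad_coord = df.index[df["lon"].isna() | df["lat"].isna()].tolist()
    if bad_coord:
        rows = [i + 1 for i in bad_coord]
        raise ValueError(f"rows with missing coordinates: {rows}")
    for col in PRESENCE_COLUMNS:
        vals = df[col]
        bad = df.index[~vals.isin((0, 1))].tolist()
        if bad:
            raise ValueError(
                f"non-binary presence flag in column {col!r} at row(s) {[i + 1 for i in bad]}"
            )
        df[col] = vals.astype(int)
    dup = df["pop_id"][df["pop_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate pop_id(s): {dup}")
    if ((df["aspect"] < 0) | (df["aspect"] > 180)).any():
        raise ValueError("aspect must be divergence from north in [0, 180] degrees")
    if (df["bio12"].dropna() < 0).any():
        raise ValueError("bio12 (annual precipitation) must be non-negative")
    df["pop_id"] = df["pop_id"].astype(str)
    return df.reset_index(drop=True)


@dataclass
class PredictorMatrices:
    """Prepared predictor blocks for the occurrence regressions.

    eco
        Eight ecological covariates (continuous ones z-scored; bio12
        cube-root transformed first; land_use kept binary).
    hist
        One column: z-scored cost distance.
    apo
        Three binary apomict-presence columns.
    kept_index
        Index of rows retained after listwise deletion of populations
        with missing covariates.
    """

    eco: pd.DataFrame
    hist: pd.DataFrame
    apo: pd.DataFrame
    kept_index: pd.Index


def zscore(x: pd.Series, name: str | None = None) -> pd.Series:
    """Scale to mean 0 and unit *sample* (n-1) variance."""
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"zero variance in continuous column {name or x.name!r}")
    return (x - x.mean()) / sd


def prepare_predictors(table: pd.DataFrame) -> PredictorMatrices:
    """Build the ecological / historical / apomict predictor matrices.

    Requires a ``cost_distance`` column (run the cost-distance stage
    first).  Populations with any missing covariate are dropped listwise
    with a logged warning, never imputed.
    """
    if "cost_distance" not in table.columns:
        raise ValueError("cost_distance not filled; run the cost-distance stage first")
    cols = list(ECO_COLUMNS) + ["cost_distance"] + list(APO_COLUMNS)
    complete = table[cols].notna().all(axis=1)
    if (~complete).any():
        dropped = table.loc[~complete, "pop_id"].tolist()
        log.warning(
            "dropping %d population(s) with missing covariates: %s",
            len(dropped),
            dropped,
        )
    sub = table.loc[complete]
    eco = pd.DataFrame(index=sub.index)
    for col in ECO_COLUMNS:
        if col == "land_use":
            eco[col] = sub[col].astype(float)  # binary, unscaled
        elif col == "bio12":
            eco[col] = zscore(np.cbrt(sub[col].astype(float)), name="bio12")
        else:
            eco[col] = zscore(sub[col].astype(float), name=col)
    hist = pd.DataFrame(
        {"cost_distance": zscore(sub["cost_distance"].astype(float), name="cost_distance")},
        index=sub.index,
    )
    apo = sub[list(APO_COLUMNS)].astype(float)
    return PredictorMatrices(eco=eco, hist=hist, apo=apo, kept_index=sub.index)


# ---------------------------------------------------------------------------
# alignments and indel coding
# ---------------------------------------------------------------------------

def _gap_events(seq: str) -> list[tuple[int, int]]:
    """Maximal gap runs of one sequence as (start, end) half-open pairs."""
    events = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            events.append((start, i))
            start = None
    if start is not None:
        events.append((start, len(seq)))
    return events


def code_indels(alignment: list[str]) -> np.ndarray:
    """Code indels as binary characters (simple indel coding).

    Each maximal gap run with identical (start, end) across sequences
    becomes one binary character; a sequence scores 1 if it carries the
    gap.  Events shared by *all* sequences are monomorphic and dropped.

    Returns an ``(n_sequences, n_events)`` 0/1 array; columns are ordered
    by (start, end).
    """
    lengths = {len(s) for s in alignment}
    if len(lengths) > 1:
        raise FormatError(f"unaligned input: sequence lengths {sorted(lengths)}")
    per_seq = [set(_gap_events(s)) for s in alignment]
    all_events = sorted(set().union(*per_seq)) if per_seq else []
    n = len(alignment)
    polymorphic = [ev for ev in all_events if sum(ev in s for s in per_seq) < n]
    out = np.zeros((n, len(polymorphic)), dtype=int)
    for row, events in enumerate(per_seq):
        for col, ev in enumerate(polymorphic):
            if ev in events:
                out[row, col] = 1
    return out


def read_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a FASTA file into (ids, sequences); duplicate ids are an error."""
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise FormatError(f"duplicate FASTA id: {rec.id!r}")
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    return ids, seqs


def write_fasta(path: str | Path, ids: list[str], seqs: list[str]) -> None:
    with open(path, "w") as fh:
        for i, s in zip(ids, seqs):
            fh.write(f">{i}\n{s}\n")


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def read_raster(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                try:
                    header[key] = float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}: bad header at line {lineno}") from exc
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise FormatError(f"{path}: bad data at line {lineno}") from exc
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing header key {key!r}")
    values = np.concatenate([np.asarray(r, dtype=float) for r in rows]) if rows else np.array([])
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise FormatError(
            f"{path}: expected {nrows * ncols} values, found {values.size}"
        )
    return Raster(
        values=values.reshape(nrows, ncols),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_raster(path: str | Path, raster: Raster) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {float(raster.xll)!r}\n")
        fh.write(f"yllcorner {float(raster.yll)!r}\n")
        fh.write(f"cellsize {float(raster.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(raster.nodata)!r}\n")
        vals = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GeoJSON source line
# ---------------------------------------------------------------------------

def read_geojson_line(path: str | Path) -> SourceLine:
    """Read a GeoJSON LineString (bare geometry, Feature or FeatureCollection)."""
    with open(path) as fh:
        obj = json.load(fh)
    geom = obj
    if obj.get("type") == "FeatureCollection":
        feats = obj.get("features", [])
        if len(feats) != 1:
            raise FormatError("expected exactly one feature with a LineString")
        geom = feats[0].get("geometry", {})
    elif obj.get("type") == "Feature":
        geom = obj.get("geometry", {})
    if geom.get("type") != "LineString":
        raise FormatError(
            f"expected a LineString geometry, found {geom.get('type')!r}"
        )
    coords = geom.get("coordinates", [])
    if len(coords) < 2:
        raise FormatError("LineString needs at least 2 coordinates")
    return SourceLine(vertices=[(c[0], c[1]) for c in coords])


def write_geojson_line(path: str | Path, line: SourceLine) -> None:
    obj = {"type": "LineString", "coordinates": [[x, y] for x, y in line.vertices]}
    with open(path, "w") as fh:
        json.dump(obj, fh)


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
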