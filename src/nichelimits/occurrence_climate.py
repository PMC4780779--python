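"""Occurrence ingestion, ESRI ASCII climate grids, and record-count filtering.

Occurrence tables are CSV files with at least the columns ``species``, ``state``
(photosynthetic pathway, ``C3`` or ``C4``), ``lon`` and ``lat`` in WGS84 decimal
degrees. Climate layers are ESRI ASCII grids (.asc), one per variable
(aridity index ``AI``, mean temperature of the warmest quarter ``MTWQ``, mean
temperature of the coldest quarter ``MTCQ``). Records are annotated with the
value of the grid cell containing them (nearest-cell, no interpolation) and
species with too few usable records are excluded before any extreme is
computed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridParseError

log = logging.getLogger(__name__)

VARIABLES = ("AI", "MTWQ", "MTCQ")
STATES = ("C3", "C4")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced record of a species with its photosynthetic state."""

    species_id: str
    state: str  # "C3" or "C4"
    lon: float
    lat: float

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")


@dataclass
class ClimateGrid:
    """A rectangular climate lattice in the ESRI ASCII grid convention.

    ``values`` is row-major with row 0 the *northernmost* row, as in the file
    format. Missing cells hold NaN internally; ``nodata_value`` is only used
    for I/O.
    """

    variable_id: str
    n_cols: int
    n_rows: int
    x_ll: float
    y_ll: float
    cell_size: float
    nodata_value: float
    values: np.ndarray  # shape (n_rows, n_cols), NaN where nodata

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_rows, self.n_cols):
            raise GridParseError(
                f"lattice shape {self.values.shape} does not match "
                f"({self.n_rows}, {self.n_cols})"
            )
        if self.cell_size <= 0:
            raise GridParseError("cell_size must be positive")
        if self.variable_id == "AI":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite < 0).any():
                raise GridParseError("AI grid contains negative values")

    @property
    def x_ur(self) -> float:
        return self.x_ll + self.n_cols * self.cell_size

    @property
    def y_ur(self) -> float:
        return self.y_ll + self.n_rows * self.cell_size


@dataclass
class ClimateSample:
    """An occurrence record annotated with per-variable climate values."""

    record: OccurrenceRecord
    values: dict[str, float | None] = field(default_factory=dict)


def read_occurrence_table(source: str | IO[str]) -> tuple[list[OccurrenceRecord], int]:
    """Read an occurrence CSV; return ``(records, n_dropped)``.

    Rows with unparseable coordinates or state, or coordinates outside the
    valid lon/lat domain, are dropped (counted and logged), preserving file
    order for the rest. A missing mandatory column is a fatal
    :class:`ConfigurationError`.
    """
    if isinstance(source, str):
        source = io.StringIO(source) if "\n" in source else open(source, "r", encoding="utf-8")
    df = pd.read_csv(source, dtype=str)
    required = {"species", "state", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"occurrence table missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    if df.empty:
        log.warning("occurrence table is empty")
        return [], 0

    records: list[OccurrenceRecord] = []
    n_dropped = 0
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    state = df["state"].str.strip()
    species = df["species"].astype(str).str.strip()
    ok = (
        lon.between(-180.0, 180.0)
        & lat.between(-90.0, 90.0)
        & state.isin(STATES)
        & (species != "")
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d occurrence row(s) with invalid coordinates or state", n_dropped)
    for sp, st, x, y in zip(species[ok], state[ok], lon[ok], lat[ok]):
        records.append(OccurrenceRecord(sp, st, float(x), float(y)))
    return records, n_dropped


def write_occurrence_table(records: Iterable[OccurrenceRecord], dest: str | IO[str]) -> None:
    """Write records back to CSV (round-trip partner of :func:`read_occurrence_table`)."""
    df = pd.DataFrame(
        [(r.species_id, r.state, r.lon, r.lat) for r in records],
        columns=["species", "state", "lon", "lat"],
    )
    df.to_csv(dest, index=False)


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(source: str | IO[str], variable_id: str) -> ClimateGrid:
    """Parse an ESRI ASCII grid. Row 0 of the lattice is the northernmost row."""
    if isinstance(source, str):
        source = io.StringIO(source) if "\n" in source else open(source, "r", encoding="utf-8")
    text = source.read().split("\n")
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridParseError(f"missing header key {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    flat = " ".join(text[i:]).split()
    if len(flat) != n_cols * n_rows:
        raise GridParseError(
            f"expected {n_cols * n_rows} values, found {len(flat)}"
        )
    values = np.array(flat, dtype=float).reshape(n_rows, n_cols)
    values[values == nodata] = np.nan
    return ClimateGrid(
        variable_id=variable_id,
        n_cols=n_cols,
        n_rows=n_rows,
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=nodata,
        values=values,
    )


def write_ascii_grid(grid: ClimateGrid, dest: str | IO[str]) -> None:
    """Write a grid in the ESRI ASCII dialect (NaN cells as the nodata sentinel)."""
    buf = io.StringIO()
    buf.write(f"ncols {grid.n_cols}\n")
    buf.write(f"nrows {grid.n_rows}\n")
    buf.write(f"xllcorner {grid.x_ll!r}\n")
    buf.write(f"yllcorner {grid.y_ll!r}\n")
    buf.write(f"cellsize {grid.cell_size!r}\n")
    buf.write(f"NODATA_value {grid.nodata_value!r}\n")
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata_value)
    for row in vals:
        buf.write(" ".join(repr(float(v)) for v in row) + "\n")
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    else:
        dest.write(buf.getvalue())


def sample_grid(grid: ClimateGrid, lon: float, lat: float) -> float | None:
    """Value of the cell containing (lon, lat), or None if off-grid or nodata.

    Cells are half-open: [x, x + cell_size) × [y, y + cell_size), so points on
    the eastern/northern outer edge fall outside the grid.
    """
    col = int(np.floor((lon - grid.x_ll) / grid.cell_size))
    row_from_bottom = int(np.floor((lat - grid.y_ll) / grid.cell_size))
    if not (0 <= col < grid.n_cols and 0 <= row_from_bottom < grid.n_rows):
        return None
    row = grid.n_rows - 1 - row_from_bottom  # row 0 = north
    v = grid.values[row, col]
    return None if np.isnan(v) else float(v)


def sample_grid_many(grid: ClimateGrid, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Vectorised :func:`sample_grid`; NaN marks missing."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    col = np.floor((lons - grid.x_ll) / grid.cell_size).astype(int)
    rfb = np.floor((lats - grid.y_ll) / grid.cell_size).astype(int)
    ok = (col >= 0) & (col < grid.n_cols) & (rfb >= 0) & (rfb < grid.n_rows)
    out = np.full(lons.shape, np.nan)
    rows = grid.n_rows - 1 - rfb[ok]
    out[ok] = grid.values[rows, col[ok]]
    return out


def attach_climate(
    records: list[OccurrenceRecord], grids: Mapping[str, ClimateGrid]
) -> list[ClimateSample]:
    """Annotate each record with the value of every configured grid.

    Missing values (off-grid or nodata) are stored as None; per-variable
    missing counts are logged. A configured variable without a grid is fatal.
    """
    if not records:
        return []
    lons = np.array([r.lon for r in records])
    lats = np.array([r.lat for r in records])
    per_var: dict[str, np.ndarray] = {}
    for var, grid in grids.items():
        if grid is None:
            raise ConfigurationError(f"no grid supplied for variable {var!r}")
        vals = sample_grid_many(grid, lons, lats)
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            log.info("variable %s: %d record(s) with missing climate value", var, n_missing)
        per_var[var] = vals
    samples = []
    for i, rec in enumerate(records):
        vals = {
            var: (None if np.isnan(per_var[var][i]) else float(per_var[var][i]))
            for var in grids
        }
        samples.append(ClimateSample(rec, vals))
    return samples


def filter_min_records(
    samples: list[ClimateSample],
    min_records: int = 6,
    per_variable: bool = True,
) -> dict[str, list[ClimateSample]]:
    """Group samples by species and drop species with too few usable records.

    With ``per_variable=True`` (default) a species is retained only if, for
    every configured variable, it has at least ``min_records`` *non-missing*
    values — guaranteeing every fitted response has that much support. With
    ``per_variable=False`` the raw record count is used instead (the
    pre-extraction variant). Excluded species are logged by name.
    """
    if min_records < 1:
        raise ConfigurationError("min_records must be >= 1")
    by_species: dict[str, list[ClimateSample]] = {}
    for s in samples:
        by_species.setdefault(s.record.species_id, []).append(s)
    kept: dict[str, list[ClimateSample]] = {}
    for sp, group in by_species.items():
        if per_variable:
            variables = group[0].values.keys()
            counts = {
                var: sum(1 for s in group if s.values.get(var) is not None)
                for var in variables
            }
            ok = all(c >= min_records for c in counts.values())
        else:
            ok = len(group) >= min_records
        if ok:
            kept[sp] = group
        else:
            log.info("excluded species %s (fewer than %d usable records)", sp, min_records)
    return kept
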