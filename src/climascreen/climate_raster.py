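"""Georeferenced single-band climate rasters and point extraction.

Grids are regular lat/lon (WGS84) rasters of one bioclimatic variable:
PDQ (precipitation of the driest quarter, mm) or MTCM (minimum
temperature of the coldest month, °C).  The canonical on-disk format is
the ESRI ASCII grid (.asc), a plain-text header followed by the value
matrix with the north-most row first.

Cell geometry convention (fixed, documented): cell (i, j) covers the
half-open box [x_ll + j*c, x_ll + (j+1)*c) x [y_ll + r*c, y_ll + (r+1)*c)
where r counts rows from the *bottom* and c is the cell size.  A point on
a shared edge therefore belongs to the higher-index (more north / more
east) cell, and the grid's outer top and right edges fall outside.
Extraction is containing-cell lookup, never interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

VARIABLES = ("PDQ", "MTCM")

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class ClimateGrid:
    """A single-variable raster; ``values[0]`` is the north-most row.

    Missing cells are NaN in memory; ``nodata_value`` is the sentinel
    used on disk.
    """

    variable: str
    values: np.ndarray  # (n_rows, n_cols) float64, NaN = nodata
    x_ll: float
    y_ll: float
    cell_size: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; expected one of {VARIABLES}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("values must be a non-empty 2-D matrix")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_ur(self) -> float:
        return self.x_ll + self.n_cols * self.cell_size

    @property
    def y_ur(self) -> float:
        return self.y_ll + self.n_rows * self.cell_size

    def cell_center_lats(self) -> np.ndarray:
        """Latitudes of row centers, row 0 (north) first."""
        return self.y_ur - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center_lons(self) -> np.ndarray:
        return self.x_ll + (np.arange(self.n_cols) + 0.5) * self.cell_size


def read_ascii_grid(path: str | Path, variable: str = "PDQ") -> ClimateGrid:
    """Parse an ESRI ASCII grid.

    The header must carry ncols/nrows/xllcorner/yllcorner/cellsize and
    optionally NODATA_value; data rows follow, north-most first.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (*_HEADER_KEYS, "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"malformed ASCII grid header in {path}: missing {missing}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    data_lines = [ln for ln in lines[i:] if ln.strip()]
    if len(data_lines) != n_rows:
        raise ValueError(f"{path}: expected {n_rows} data rows, found {len(data_lines)}")
    rows = []
    for ln in data_lines:
        row = np.array(ln.split(), dtype=float)
        if row.size != n_cols:
            raise ValueError(f"{path}: row has {row.size} values, expected {n_cols}")
        rows.append(row)
    values = np.vstack(rows)
    values[values == nodata] = np.nan
    return ClimateGrid(
        variable=variable,
        values=values,
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=nodata,
    )


def write_ascii_grid(grid: ClimateGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid; values printed with full float precision
    so a write/read cycle round-trips exactly."""
    out = np.where(np.isnan(grid.values), grid.nodata_value, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_ll:.17g}\n")
        fh.write(f"yllcorner {grid.y_ll:.17g}\n")
        fh.write(f"cellsize {grid.cell_size:.17g}\n")
        fh.write(f"NODATA_value {grid.nodata_value:.17g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def extract_at_points(
    grid: ClimateGrid, lats: Sequence[float], lons: Sequence[float]
) -> np.ndarray:
    """Containing-cell values at points; NaN for outside-extent or nodata."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    col = np.floor((lons - grid.x_ll) / grid.cell_size).astype(int)
    row_from_bottom = np.floor((lats - grid.y_ll) / grid.cell_size).astype(int)
    row = grid.n_rows - 1 - row_from_bottom
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    out = np.full(lats.shape, np.nan)
    out[inside] = grid.values[row[inside], col[inside]]
    return out


@dataclass(frozen=True)
class SpecimenClimate:
    """An occurrence record joined with its two climate values (both present)."""

    record: "OccurrenceRecord"  # noqa: F821 - forward ref to occurrence_io
    pdq: float  # mm
    mtcm: float  # °C

    @property
    def species(self) -> str:
        return self.record.species


def link_climate(
    records: Iterable,
    pdq_grid: ClimateGrid,
    mtcm_grid: ClimateGrid,
) -> tuple[list[SpecimenClimate], int]:
    """Join occurrences with PDQ and MTCM; drop (and count) records where
    either value is missing."""
    if pdq_grid.variable != "PDQ":
        raise ValueError(f"pdq_grid carries variable {pdq_grid.variable!r}, expected 'PDQ'")
    if mtcm_grid.variable != "MTCM":
        raise ValueError(f"mtcm_grid carries variable {mtcm_grid.variable!r}, expected 'MTCM'")
    records = list(records)
    if not records:
        return [], 0
    lats = [r.lat for r in records]
    lons = [r.lon for r in records]
    pdq = extract_at_points(pdq_grid, lats, lons)
    mtcm = extract_at_points(mtcm_grid, lats, lons)
    linked: list[SpecimenClimate] = []
    n_dropped = 0
    for rec, p, t in zip(records, pdq, mtcm):
        if np.isnan(p) or np.isnan(t):
            n_dropped += 1
        else:
            linked.append(SpecimenClimate(record=rec, pdq=float(p), mtcm=float(t)))
    return linked, n_dropped
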