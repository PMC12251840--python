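"""Reading, validating and writing occurrence record tables.

Input is a delimited text table with Darwin-Core-style column names
(``species``, ``decimalLatitude``, ``decimalLongitude``) in WGS84.
Rows with a blank species label, unparseable coordinates, or coordinates
outside [-90, 90] x [-180, 180] are dropped and counted, never fatal.
No taxonomic resolution is attempted: species labels are compared
exactly after whitespace trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

#: default Darwin-Core-style column mapping
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "species": "species",
    "lat": "decimalLatitude",
    "lon": "decimalLongitude",
    "record_id": "record_id",
}


@dataclass(frozen=True)
class OccurrenceRecord:
    """One specimen: binomial label plus WGS84 decimal coordinates."""

    species: str
    lat: float
    lon: float
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label must be non-empty")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    drop_zero_zero: bool = False,
) -> tuple[list[OccurrenceRecord], int]:
    """Read occurrences, dropping and counting invalid rows.

    Parameters
    ----------
    path : file path to a CSV/TSV table with a header row.
    column_map : maps the keys ``species``/``lat``/``lon`` (optionally
        ``record_id``) to column names in the file; Darwin-Core defaults.
    delimiter : field separator ("," for CSV, "\\t" for GBIF exports).
    drop_zero_zero : strict mode dropping the (0, 0) null-island point;
        off by default — an exact 0,0 coordinate is otherwise valid.

    Returns
    -------
    (records, dropped_count) with input row order preserved and
    ``dropped_count + len(records)`` equal to the number of data rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    needed = [cmap["species"], cmap["lat"], cmap["lon"]]
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: mapped columns absent from header: {absent}")
    id_col = cmap.get("record_id")
    if id_col is not None and id_col not in df.columns:
        id_col = None

    lat = pd.to_numeric(df[cmap["lat"]], errors="coerce")
    lon = pd.to_numeric(df[cmap["lon"]], errors="coerce")
    species = df[cmap["species"]].str.strip()
    ok = (
        lat.notna()
        & lon.notna()
        & lat.between(-90.0, 90.0)
        & lon.between(-180.0, 180.0)
        & (species != "")
    )
    if drop_zero_zero:
        ok &= ~((lat == 0.0) & (lon == 0.0))

    records = [
        OccurrenceRecord(
            species=species.iat[i],
            lat=float(lat.iat[i]),
            lon=float(lon.iat[i]),
            record_id=(str(df[id_col].iat[i]) if id_col is not None else None),
        )
        for i in df.index[ok]
    ]
    return records, int((~ok).sum())


def write_occurrences(
    records: Iterable[OccurrenceRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records with the default Darwin-Core-style header; floats are
    written with repr precision so read(write(x)) round-trips exactly."""
    records = list(records)
    with_id = any(r.record_id is not None for r in records)
    cols = {
        "species": [r.species for r in records],
        "decimalLatitude": [repr(r.lat) for r in records],
        "decimalLongitude": [repr(r.lon) for r in records],
    }
    if with_id:
        cols["record_id"] = [r.record_id or "" for r in records]
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)
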