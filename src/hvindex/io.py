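"""Readers and writers for the delimited-text and GeoJSON formats.

All tabular formats are comma-separated UTF-8 with a header row; missing
cells are empty strings. District-by-indicator tables are carried in
memory as pandas DataFrames indexed by ``district_id`` with NaN marking
missing cells.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import RosterError, TableParseError
from .schema import Schema

__all__ = [
    "read_indicator_table", "write_indicator_table",
    "read_province_values", "write_province_values",
    "read_monthly_climate", "write_monthly_climate",
    "read_events", "write_events",
    "write_results", "read_results",
    "write_geojson_grid", "read_geojson",
]


def read_indicator_table(path: str | Path, schema: Schema,
                         roster_ids: Iterable[str] | None = None,
                         ) -> pd.DataFrame:
    """Read a district-by-indicator table.

    One row per district, first column ``district_id``, remaining header
    names must be schema indicator ids (or the auxiliary per-hazard
    frequency columns). Blank cells become NaN. Raises
    :class:`TableParseError` with row/column coordinates for non-numeric
    cells and :class:`RosterError` for unknown districts.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "district_id" not in raw.columns:
        raise TableParseError(f"{path}: missing district_id column")
    allowed = set(schema.ids) | set(schema.aux_hazard_ids())
    unknown = [c for c in raw.columns if c != "district_id"
               and c not in allowed]
    if unknown:
        raise TableParseError(
            f"{path}: columns not in schema: {unknown}")
    if raw["district_id"].duplicated().any():
        dups = raw.loc[raw["district_id"].duplicated(), "district_id"]
        raise TableParseError(
            f"{path}: duplicate district rows: {sorted(set(dups))}")
    table = raw.set_index("district_id")
    if roster_ids is not None:
        bad = set(table.index) - set(roster_ids)
        if bad:
            raise RosterError(
                f"{path}: districts not in roster: {sorted(bad)}")
    parsed = {}
    for col in table.columns:
        cells = table[col].str.strip()
        numeric = pd.to_numeric(cells.replace("", np.nan), errors="coerce")
        bad_mask = numeric.isna() & (cells != "")
        if bad_mask.any():
            row = table.index[bad_mask.to_numpy()][0]
            raise TableParseError(
                f"{path}: non-numeric value {table.loc[row, col]!r} at "
                f"district {row!r}, indicator {col!r}",
                row=str(row), column=col)
        parsed[col] = numeric
    out = pd.DataFrame(parsed, index=table.index)
    out.index.name = "district_id"
    return out


def write_indicator_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a district-by-indicator table (NaN -> empty cell)."""
    out = table.copy()
    out.index.name = "district_id"
    out.to_csv(path, na_rep="")


def read_province_values(path: str | Path) -> pd.DataFrame:
    """Province-level indicator values: rows keyed by ``province_id``."""
    df = pd.read_csv(path).set_index("province_id")
    return df


def write_province_values(values: pd.DataFrame, path: str | Path) -> None:
    out = values.copy()
    out.index.name = "province_id"
    out.to_csv(path, na_rep="")


_CLIMATE_COLUMNS = ["district_id", "variable", "year", "month", "value"]


def read_monthly_climate(path: str | Path) -> pd.DataFrame:
    """Monthly climate series in long form
    (district_id, variable, year, month, value)."""
    df = pd.read_csv(path)
    missing = set(_CLIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise TableParseError(
            f"{path}: climate file missing columns {sorted(missing)}")
    return df[_CLIMATE_COLUMNS]


def write_monthly_climate(climate: pd.DataFrame, path: str | Path) -> None:
    climate[_CLIMATE_COLUMNS].to_csv(path, index=False)


_EVENT_COLUMNS = ["district_id", "hazard", "year"]


def read_events(path: str | Path) -> pd.DataFrame:
    """Extreme-event records (district_id, hazard, year)."""
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise TableParseError(
            f"{path}: event file missing columns {sorted(missing)}")
    return df[_EVENT_COLUMNS]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[_EVENT_COLUMNS].to_csv(path, index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write per-district scores and classes.

    ``results`` is indexed by district_id with at least columns
    province_id, E, S, AC, HVI, hvi_class; excluded districts carry the
    class marker ``"excluded"``. Numbers are serialized at full (repr)
    precision so a read round-trips to <= 1e-12 relative error.
    """
    out = results.copy()
    out.index.name = "district_id"
    out.to_csv(path, na_rep="")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results file written by :func:`write_results`.

    Class columns (``*_class``) stay as strings ("1".."5" / "excluded");
    numeric columns are parsed as floats.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.set_index("district_id")
    for col in df.columns:
        if "_class" in col or col == "province_id":
            df[col] = df[col].replace("", np.nan)
            continue
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    return df


# ---------------------------------------------------------------------------
# GeoJSON (RFC 7946)
# ---------------------------------------------------------------------------

def write_geojson_grid(district_ids: Sequence[str], path: str | Path,
                       ncols: int | None = None,
                       cell_deg: float = 0.5,
                       origin: tuple[float, float] = (30.0, -27.0)) -> dict:
    """Write a toy GeoJSON of rectangular district polygons on a grid.

    Purely for map smoke tests; cells are laid out row-major from
    ``origin`` (lon, lat in WGS84). Returns the GeoJSON mapping.
    """
    n = len(district_ids)
    if ncols is None:
        ncols = int(np.ceil(np.sqrt(n)))
    lon0, lat0 = origin
    features = []
    for k, did in enumerate(district_ids):
        r, c = divmod(k, ncols)
        x0, y0 = lon0 + c * cell_deg, lat0 + r * cell_deg
        ring = [[x0, y0], [x0 + cell_deg, y0],
                [x0 + cell_deg, y0 + cell_deg], [x0, y0 + cell_deg],
                [x0, y0]]
        features.append({
            "type": "Feature",
            "properties": {"district_id": did},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    geojson = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(geojson))
    return geojson


def read_geojson(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise TableParseError(f"{path}: not a GeoJSON FeatureCollection")
    return data
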