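"""Raw inputs -> complete normalized indicator matrix.

Four stages live here:

* ``annual_variation`` — total change of a climate variable over the record,
  from monthly series (annual means, then either an OLS-trend total change
  or a first-decade/last-decade endpoint difference);
* ``hazard_frequency`` — event counts per district/hazard inside a year
  window;
* ``impute_missing`` — hierarchical completion: province-level values
  broadcast to districts, sporadic gaps filled with the province mean of
  observed districts, whole-province gaps with the national mean (flagged);
* ``min_max_normalize`` — per-indicator rescaling Y = (X - Xmin)/(Xmax -
  Xmin) to [0, 1], reflecting Y <- 1 - Y for indicators whose raw value
  runs opposite to their component's meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import HVIError, RosterError
from .schema import (Schema, SpatialLevel, Direction, HAZARDS,
                     hazard_freq_column, COMBINED_HAZARD_INDICATOR,
                     CLIMATE_INDICATORS)

__all__ = [
    "annual_variation", "climate_variation_table",
    "hazard_frequency", "hazard_frequency_table",
    "impute_missing", "ImputationResult",
    "min_max_normalize", "NormalizedTable",
]


# ---------------------------------------------------------------------------
# Climate variation
# ---------------------------------------------------------------------------

def _annual_means(monthly: pd.DataFrame) -> pd.Series:
    counts = monthly.groupby("year")["month"].nunique()
    complete = counts.index[counts == 12]
    if len(complete) < len(counts):
        dropped = sorted(set(counts.index) - set(complete))
        warnings.warn(
            f"dropping incomplete years {dropped} from monthly series",
            stacklevel=3)
    means = (monthly[monthly["year"].isin(complete)]
             .groupby("year")["value"].mean())
    return means.sort_index()


def annual_variation(monthly: pd.DataFrame,
                     method: str = "trend_total_change",
                     k: int = 10) -> float:
    """Total change of a variable over the record, in its own units.

    ``monthly`` has columns year, month, value for one district and one
    variable. Monthly values are first averaged into calendar-year means
    (incomplete years are dropped with a warning); then

    * ``trend_total_change``: OLS slope of annual means on year, times
      (Y - 1) where Y is the number of complete years — the fitted change
      across the record;
    * ``endpoint_difference``: mean of the last ``k`` annual means minus
      mean of the first ``k`` (k clipped to floor(Y/2)).
    """
    means = _annual_means(monthly)
    y = len(means)
    if y < 2:
        raise HVIError(
            f"annual_variation needs >= 2 complete years, got {y}")
    if method == "trend_total_change":
        years = means.index.to_numpy(dtype=float)
        slope = np.polyfit(years, means.to_numpy(), 1)[0]
        return float(slope * (y - 1))
    if method == "endpoint_difference":
        k = max(1, min(int(k), y // 2))
        vals = means.to_numpy()
        return float(vals[-k:].mean() - vals[:k].mean())
    raise HVIError(f"unknown variation method {method!r}")


_VARIABLE_TO_INDICATOR = {
    "temperature": "temp_variation",
    "rainfall": "rain_variation",
    "relative_humidity": "rh_variation",
}


def climate_variation_table(climate: pd.DataFrame,
                            method: str = "trend_total_change",
                            k: int = 10) -> pd.DataFrame:
    """Vectorized ``annual_variation`` over a long climate table.

    Returns a district-by-indicator frame with columns temp_variation,
    rain_variation, rh_variation.
    """
    counts = climate.groupby(["district_id", "variable", "year"])["month"] \
                    .nunique()
    complete = counts[counts == 12].reset_index()[
        ["district_id", "variable", "year"]]
    sub = climate.merge(complete, on=["district_id", "variable", "year"])
    annual = (sub.groupby(["district_id", "variable", "year"])["value"]
              .mean().reset_index())

    def _total_change(g: pd.DataFrame) -> float:
        yrs = g["year"].to_numpy(dtype=float)
        vals = g["value"].to_numpy()
        y = len(yrs)
        if y < 2:
            raise HVIError(
                "climate series has fewer than 2 complete years for "
                f"district {g.name[0]!r}, variable {g.name[1]!r}")
        if method == "trend_total_change":
            t = yrs - yrs.mean()
            slope = float(t @ (vals - vals.mean()) / (t @ t))
            return slope * (y - 1)
        kk = max(1, min(int(k), y // 2))
        return float(vals[-kk:].mean() - vals[:kk].mean())

    annual = annual.sort_values(["district_id", "variable", "year"])
    out = (annual.groupby(["district_id", "variable"])
           .apply(_total_change, include_groups=False)
           .unstack("variable"))
    out = out.rename(columns=_VARIABLE_TO_INDICATOR)
    out.index.name = "district_id"
    out.columns.name = None
    return out[[c for c in CLIMATE_INDICATORS if c in out.columns]]


# ---------------------------------------------------------------------------
# Hazard frequencies
# ---------------------------------------------------------------------------

def hazard_frequency(events: pd.DataFrame, district_id: str, hazard: str,
                     window: tuple[int, int] = (1980, 2019)) -> int:
    """Count events of ``hazard`` in ``district_id`` with year inside the
    closed ``window``."""
    lo, hi = window
    if lo > hi:
        raise HVIError(f"invalid hazard window {window}")
    if events.empty:
        return 0
    m = ((events["district_id"] == district_id)
         & (events["hazard"] == hazard)
         & (events["year"] >= lo) & (events["year"] <= hi))
    return int(m.sum())


def hazard_frequency_table(events: pd.DataFrame,
                           district_ids,
                           window: tuple[int, int] = (1980, 2019),
                           ) -> pd.DataFrame:
    """Per-hazard frequency columns plus the combined extreme-event count.

    The combined column is the sum of the three per-hazard counts; after
    min-max normalization this equals using their mean.
    """
    lo, hi = window
    if lo > hi:
        raise HVIError(f"invalid hazard window {window}")
    idx = pd.Index(district_ids, name="district_id")
    out = pd.DataFrame(0.0, index=idx,
                       columns=[hazard_freq_column(h) for h in HAZARDS])
    if not events.empty:
        sub = events[(events["year"] >= lo) & (events["year"] <= hi)]
        counts = sub.groupby(["district_id", "hazard"]).size()
        for h in HAZARDS:
            if h in counts.index.get_level_values("hazard"):
                col = counts.xs(h, level="hazard")
                out.loc[col.index.intersection(idx),
                        hazard_freq_column(h)] = col
    out[COMBINED_HAZARD_INDICATOR] = out.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    """Completed table plus provenance flags.

    ``flags`` has the table's shape with values in {"observed",
    "province_broadcast", "province_mean", "national_mean"}.
    """

    table: pd.DataFrame
    flags: pd.DataFrame
    n_imputed: int = 0
    national_fallback: list[str] = field(default_factory=list)


def impute_missing(table: pd.DataFrame, schema: Schema,
                   roster: pd.DataFrame | dict,
                   policy: tuple[str, ...] = ("province_broadcast",
                                              "province_mean",
                                              "national_mean"),
                   province_values: pd.DataFrame | None = None,
                   ) -> ImputationResult:
    """Hierarchically complete a district-by-indicator table.

    1. province-level indicators: every district inherits its province's
       single value from ``province_values``;
    2. sporadic district gaps: arithmetic mean of observed values among
       same-province districts for that indicator;
    3. fallback when an entire province is unobserved for an indicator:
       national mean of observed districts (flagged).

    Observed cells are never altered. An indicator with no observed value
    anywhere (and no province-level source) is an error.
    """
    if isinstance(roster, dict):
        province_map = pd.Series(roster)
    else:
        province_map = roster["province_id"]
    missing_roster = set(table.index) - set(province_map.index)
    if missing_roster:
        raise RosterError(
            f"districts without a province: {sorted(missing_roster)}")
    provinces = province_map.reindex(table.index)

    out = table.copy()
    flags = pd.DataFrame("observed", index=table.index,
                         columns=table.columns)
    flags = flags.where(table.notna(), other="missing")
    n_imputed = 0
    national_fallback: list[str] = []

    for col in table.columns:
        in_schema = col in schema
        level = (schema[col].spatial_level if in_schema
                 else SpatialLevel.DISTRICT)
        mask = out[col].isna()

        if (level is SpatialLevel.PROVINCE
                and "province_broadcast" in policy
                and province_values is not None
                and col in province_values.columns):
            prov_vals = province_values[col]
            fill = provinces.map(prov_vals)
            to_fill = mask & fill.notna()
            out.loc[to_fill, col] = fill[to_fill]
            flags.loc[to_fill, col] = "province_broadcast"
            n_imputed += int(to_fill.sum())
            mask = out[col].isna()

        if mask.any() and "province_mean" in policy:
            prov_means = out.groupby(provinces)[col].mean()
            fill = provinces.map(prov_means)
            to_fill = mask & fill.notna()
            out.loc[to_fill, col] = fill[to_fill]
            flags.loc[to_fill, col] = "province_mean"
            n_imputed += int(to_fill.sum())
            mask = out[col].isna()

        if mask.any() and "national_mean" in policy:
            national = out[col].mean()
            if pd.notna(national):
                out.loc[mask, col] = national
                flags.loc[mask, col] = "national_mean"
                n_imputed += int(mask.sum())
                national_fallback.append(col)
                mask = out[col].isna()

        if mask.any():
            raise HVIError(
                f"indicator {col!r} has no observed values anywhere; "
                "cannot impute")

    return ImputationResult(table=out, flags=flags, n_imputed=n_imputed,
                            national_fallback=sorted(set(national_fallback)))


# ---------------------------------------------------------------------------
# Min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedTable:
    """A complete [0,1] indicator matrix plus per-indicator records.

    ``records`` is indexed by indicator id with columns x_min, x_max,
    direction, degenerate, dropped. Dropped indicators (degenerate under
    the ``drop_indicator`` policy) are absent from ``data`` but kept in
    ``records``; downstream weights are renormalized over survivors.
    """

    data: pd.DataFrame
    records: pd.DataFrame
    schema: Schema

    @property
    def dropped(self) -> list[str]:
        return list(self.records.index[self.records["dropped"]])

    def surviving(self, ids) -> list[str]:
        return [i for i in ids if i in self.data.columns]


def min_max_normalize(table: pd.DataFrame, schema: Schema,
                      degenerate_policy: str = "zero_fill",
                      ) -> NormalizedTable:
    """Rescale every indicator to [0, 1] across districts.

    Y_i = (X_i - X_min) / (X_max - X_min), with X_min/X_max taken over the
    table's districts; indicators flagged ``higher_is_less`` are then
    reflected (Y <- 1 - Y). Degenerate indicators (X_max == X_min) are
    zero-filled or dropped per policy, with a warning either way.
    """
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise HVIError(
            f"cannot normalize a table with missing cells (columns {bad}); "
            "run impute_missing first")
    data = {}
    records = []
    for col in table.columns:
        direction = schema.direction_of(col)  # SchemaError if unknown
        x = table[col].astype(float)
        x_min, x_max = float(x.min()), float(x.max())
        degenerate = x_max == x_min
        dropped = False
        if degenerate:
            warnings.warn(
                f"indicator {col!r} is degenerate (constant at {x_min}); "
                f"policy={degenerate_policy}", stacklevel=2)
            if degenerate_policy == "drop_indicator":
                dropped = True
            else:
                data[col] = pd.Series(0.0, index=table.index)
        else:
            y = (x - x_min) / (x_max - x_min)
            if direction is Direction.HIGHER_IS_LESS:
                y = 1.0 - y
            data[col] = y
        records.append({"indicator_id": col, "x_min": x_min,
                        "x_max": x_max, "direction": direction.value,
                        "degenerate": degenerate, "dropped": dropped})
    rec = pd.DataFrame(records).set_index("indicator_id")
    return NormalizedTable(data=pd.DataFrame(data, index=table.index),
                           records=rec, schema=schema)
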