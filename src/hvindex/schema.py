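"""Indicator schema and administrative roster types.

The packaged default schema encodes the 32-indicator taxonomy used to score
district-level climate-health vulnerability: 4 exposure indicators (three
climate-variable variations plus one combined extreme-event frequency),
12 sensitivity indicators (ecosystem risk, demography, disease burden) and
16 adaptive-capacity indicators (financial resources, health services,
human resources, water and sanitation, social capital).

Each indicator carries a ``direction`` stating how its raw value relates to
its component's meaning: ``higher_is_more`` means a larger raw value means
more of the component (more exposure, more sensitivity, more adaptive
capacity); ``higher_is_less`` indicators (e.g. inhabitants per health unit)
are reflected during normalization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import SchemaError

__all__ = [
    "Component", "Direction", "SpatialLevel", "IndicatorDef", "Schema",
    "District", "Province", "load_schema", "default_schema",
    "PROVINCES", "HAZARDS", "hazard_freq_column", "CLIMATE_INDICATORS",
    "COMBINED_HAZARD_INDICATOR",
]


class Component(str, Enum):
    EXPOSURE = "exposure"
    SENSITIVITY = "sensitivity"
    ADAPTIVE_CAPACITY = "adaptive_capacity"


class Direction(str, Enum):
    HIGHER_IS_MORE = "higher_is_more"
    HIGHER_IS_LESS = "higher_is_less"


class SpatialLevel(str, Enum):
    DISTRICT = "district"
    PROVINCE = "province"


@dataclass(frozen=True)
class IndicatorDef:
    """One indicator of the vulnerability schema."""

    indicator_id: str
    label: str
    component: Component
    determinant: str
    direction: Direction = Direction.HIGHER_IS_MORE
    spatial_level: SpatialLevel = SpatialLevel.DISTRICT
    period: str = ""


HAZARDS = ("drought", "flood", "cyclone")

#: Exposure indicators built from monthly climate series.
CLIMATE_INDICATORS = ("temp_variation", "rain_variation", "rh_variation")

#: Combined extreme-event frequency indicator (sum of per-hazard counts).
COMBINED_HAZARD_INDICATOR = "extreme_event_freq"


def hazard_freq_column(hazard: str) -> str:
    """Auxiliary per-hazard frequency column name (not one of the 32)."""
    if hazard not in HAZARDS:
        raise ValueError(
            f"unknown hazard {hazard!r}; expected one of {HAZARDS}")
    return f"hazard_freq_{hazard}"


# (id, label, component, determinant, direction, level, period)
_M, _L = Direction.HIGHER_IS_MORE, Direction.HIGHER_IS_LESS
_D, _P = SpatialLevel.DISTRICT, SpatialLevel.PROVINCE
_E, _S, _A = (Component.EXPOSURE, Component.SENSITIVITY,
              Component.ADAPTIVE_CAPACITY)

_DEFAULT_ROWS = [
    # -- exposure (4) ------------------------------------------------------
    ("temp_variation", "Average temperature variation", _E,
     "Changes on rainfall, temperature and RH", _M, _D, "1970-2016"),
    ("rain_variation", "Average rainfall variation", _E,
     "Changes on rainfall, temperature and RH", _M, _D, "1970-2016"),
    ("rh_variation", "Average variation in relative humidity", _E,
     "Changes on rainfall, temperature and RH", _M, _D, "1970-2016"),
    (COMBINED_HAZARD_INDICATOR,
     "Frequency of floods, droughts and cyclones", _E,
     "Extreme events", _M, _D, "1980-2019"),
    # -- sensitivity (12) --------------------------------------------------
    ("cholera_outbreaks", "Frequency of cholera outbreaks", _S,
     "Natural capital (ecosystem/geography risks)", _M, _D, "2014-2019"),
    ("food_insecurity", "Frequency of food insecurity episodes", _S,
     "Natural capital (ecosystem/geography risks)", _M, _D, "2016-2019"),
    ("pop_density", "Population density", _S,
     "Natural capital (demography and vulnerable population)", _M, _D,
     "2017"),
    ("pct_under5", "Percent of children under five", _S,
     "Natural capital (demography and vulnerable population)", _M, _D,
     "2017"),
    ("pct_age5_15", "Percent of children aged 5-15", _S,
     "Natural capital (demography and vulnerable population)", _M, _D,
     "2017"),
    ("pct_women", "Percent of women", _S,
     "Natural capital (demography and vulnerable population)", _M, _D,
     "2017"),
    ("pct_over60", "Percent of elderly people (over 60)", _S,
     "Natural capital (demography and vulnerable population)", _M, _D,
     "2017"),
    ("hiv_positivity", "HIV positivity rate", _S,
     "Vulnerable population due to health conditions", _M, _D, "2017-2018"),
    ("tb_rate", "Rate of reported tuberculosis cases", _S,
     "Vulnerable population due to health conditions", _M, _D, "2017-2018"),
    ("malnutrition_rate",
     "Acute and chronic malnutrition cases per 100,000", _S,
     "Vulnerable population due to health conditions", _M, _D, "2017-2018"),
    ("malaria_rate", "Malaria cases per 100 inhabitants", _S,
     "Vulnerable population due to health conditions", _M, _D, "2017-2018"),
    ("diarrhea_rate", "Diarrheal disease cases per 100,000", _S,
     "Vulnerable population due to health conditions", _M, _D, "2017-2018"),
    # -- adaptive capacity (16) --------------------------------------------
    ("health_expenditure_pc",
     "Per capita public sector health expenditure", _A,
     "Financial resources", _M, _D, "2018"),
    ("per_capita_expenditure", "Per capita expenditure", _A,
     "Financial resources", _M, _P, "2014"),
    ("inhabitants_per_health_unit",
     "Inhabitants per health unit", _A,
     "Health services", _L, _D, "2018"),
    ("pct_within_health_radius",
     "Percent of population within coverage radius of a health facility",
     _A, "Health services", _M, _D, "2018"),
    ("medical_workers_per_100k", "Medical workers per 100,000", _A,
     "Human resources", _M, _D, "2018"),
    ("nursing_workers_per_100k", "Nursing workers per 100,000", _A,
     "Human resources", _M, _D, "2018"),
    ("midwifery_workers_per_100k", "Midwifery workers per 100,000", _A,
     "Human resources", _M, _D, "2018"),
    ("inhabitants_per_ape",
     "Inhabitants per elementary multipurpose health agent", _A,
     "Human resources", _L, _D, "2019"),
    ("pct_safe_water", "Percent with access to safe water sources", _A,
     "Water and sanitation", _M, _D, "2017"),
    ("pct_safe_latrines", "Percent with access to safe latrines", _A,
     "Water and sanitation", _M, _D, "2017"),
    ("pct_literate_men", "Percent literate population, men", _A,
     "Social capital", _M, _D, "2017"),
    ("pct_primary_men", "Percent with primary education, men", _A,
     "Social capital", _M, _D, "2017"),
    ("pct_secondary_men", "Percent with secondary education, men", _A,
     "Social capital", _M, _D, "2017"),
    ("pct_literate_women", "Percent literate population, women", _A,
     "Social capital", _M, _D, "2017"),
    ("pct_primary_women", "Percent with primary education, women", _A,
     "Social capital", _M, _D, "2017"),
    ("pct_secondary_women", "Percent with secondary education, women", _A,
     "Social capital", _M, _D, "2017"),
]


class Schema:
    """A validated collection of :class:`IndicatorDef`.

    Iterable over its indicators; indexable by ``indicator_id``.
    """

    def __init__(self, indicators: Iterable[IndicatorDef]):
        self._indicators = list(indicators)
        self._by_id: dict[str, IndicatorDef] = {}
        for ind in self._indicators:
            if ind.indicator_id in self._by_id:
                raise SchemaError(
                    f"duplicate indicator_id {ind.indicator_id!r}")
            if not isinstance(ind.component, Component):
                raise SchemaError(
                    f"unknown component {ind.component!r} for "
                    f"{ind.indicator_id!r}")
            self._by_id[ind.indicator_id] = ind

    def __iter__(self) -> Iterator[IndicatorDef]:
        return iter(self._indicators)

    def __len__(self) -> int:
        return len(self._indicators)

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def __getitem__(self, indicator_id: str) -> IndicatorDef:
        try:
            return self._by_id[indicator_id]
        except KeyError:
            raise SchemaError(f"unknown indicator {indicator_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [i.indicator_id for i in self._indicators]

    def component_ids(self, component: Component | str) -> list[str]:
        component = Component(component)
        return [i.indicator_id for i in self._indicators
                if i.component is component]

    def determinants(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self._indicators:
            seen.setdefault(i.determinant)
        return list(seen)

    def determinant_ids(self, determinant: str) -> list[str]:
        return [i.indicator_id for i in self._indicators
                if i.determinant == determinant]

    def province_level_ids(self) -> list[str]:
        return [i.indicator_id for i in self._indicators
                if i.spatial_level is SpatialLevel.PROVINCE]

    def aux_hazard_ids(self) -> list[str]:
        """Per-hazard frequency columns usable alongside the schema."""
        return [hazard_freq_column(h) for h in HAZARDS]

    def direction_of(self, column: str) -> Direction:
        """Direction for a schema indicator or auxiliary hazard column."""
        if column in self._by_id:
            return self._by_id[column].direction
        if column in self.aux_hazard_ids():
            return Direction.HIGHER_IS_MORE
        raise SchemaError(f"unknown column {column!r}")


def default_schema() -> Schema:
    """The packaged 32-indicator schema (4 exposure / 12 sensitivity /
    16 adaptive capacity)."""
    return Schema(IndicatorDef(*row) for row in _DEFAULT_ROWS)


_REQUIRED_COLUMNS = ("indicator_id", "label", "component", "determinant",
                     "direction", "spatial_level", "period")


def load_schema(path: str | Path | None = None) -> Schema:
    """Load an indicator schema.

    ``path=None`` returns the packaged default schema. Otherwise reads a
    comma-delimited file with header columns ``indicator_id, label,
    component, determinant, direction, spatial_level, period``.
    """
    if path is None:
        return default_schema()
    path = Path(path)
    indicators = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(
                f"schema file {path} missing columns: {sorted(missing)}")
        for row in reader:
            try:
                component = Component(row["component"])
                direction = Direction(row["direction"])
                level = SpatialLevel(row["spatial_level"])
            except ValueError as exc:
                raise SchemaError(
                    f"invalid enum value in schema row "
                    f"{row['indicator_id']!r}: {exc}") from None
            indicators.append(IndicatorDef(
                indicator_id=row["indicator_id"], label=row["label"],
                component=component, determinant=row["determinant"],
                direction=direction, spatial_level=level,
                period=row.get("period", "")))
    return Schema(indicators)


def write_schema(schema: Schema, path: str | Path) -> None:
    """Write a schema to the delimited format read by :func:`load_schema`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REQUIRED_COLUMNS)
        for ind in schema:
            writer.writerow([
                ind.indicator_id, ind.label, ind.component.value,
                ind.determinant, ind.direction.value,
                ind.spatial_level.value, ind.period])


# ---------------------------------------------------------------------------
# Administrative roster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Province:
    province_id: str
    name: str
    region: str          # north / centre / south
    coastal: bool


#: The 11 provinces, with region and coastline attributes used by the
#: synthetic generator's hazard gradients.
PROVINCES = (
    Province("P01", "Niassa", "north", False),
    Province("P02", "Cabo Delgado", "north", True),
    Province("P03", "Nampula", "north", True),
    Province("P04", "Zambezia", "centre", True),
    Province("P05", "Tete", "centre", False),
    Province("P06", "Manica", "centre", False),
    Province("P07", "Sofala", "centre", True),
    Province("P08", "Inhambane", "south", True),
    Province("P09", "Gaza", "south", True),
    Province("P10", "Maputo Provincia", "south", True),
    Province("P11", "Maputo Cidade", "south", True),
)


@dataclass(frozen=True)
class District:
    """One district of the assessment roster.

    ``population``, ``coastal`` and ``region`` exist for the synthetic
    generator; real-data assessments only need the identifiers and the
    capital flag.
    """

    district_id: str
    name: str
    province_id: str
    is_capital: bool = False
    population: int = 0
    coastal: bool = False
    region: str = "centre"

    def __post_init__(self):
        if self.population < 0:
            raise RosterError(
                f"district {self.district_id!r} has negative population")


def roster_frame(districts: Iterable[District]):
    """Roster as a DataFrame indexed by district_id (import-light helper)."""
    import pandas as pd

    df = pd.DataFrame([{
        "district_id": d.district_id, "name": d.name,
        "province_id": d.province_id, "is_capital": d.is_capital,
        "population": d.population, "coastal": d.coastal,
        "region": d.region} for d in districts]).set_index("district_id")
    if df.index.has_duplicates:
        from .errors import RosterError
        raise RosterError("duplicate district_id in roster")
    return df


def province_of(districts: Iterable[District]) -> Mapping[str, str]:
    return {d.district_id: d.province_id for d in districts}
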