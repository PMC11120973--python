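"""Synthetic district panels with the structure the assessment assumes.

A single latent vulnerability factor per district — a regional gradient
(south high, north low), a province random effect and a district effect —
drives every indicator: exposure and sensitivity indicators increase with
the latent factor, adaptive-capacity indicators decrease with it, and one
capital district per province receives an additive adaptive-capacity
advantage (mirroring the outlying urban capitals of real assessments).
Extreme-event counts are Poisson with a coastal multiplier for cyclones
and a southern multiplier for droughts; monthly climate series are a
seasonal sinusoid plus a latent-linked linear trend plus noise.

All indicator transforms are strictly monotone (logistic for percentages,
exponential for rates), so with the noise turned off the rank order of
any generated indicator equals the rank order of the latent factor —
which is what makes "the HVI recovers true vulnerability" a testable
property. The held-out latent score is carried on the panel for exactly
that validation and is never an input to the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as hio
from .errors import ConfigError
from .schema import (Schema, District, PROVINCES, HAZARDS, default_schema,
                     roster_frame)

__all__ = ["GeneratorSpec", "SyntheticPanel", "generate",
           "generate_monthly_climate", "load_panel_dir"]

_REGION_OFFSET = {"north": -1.4, "centre": 0.0, "south": 1.4}

#: slope scale per year, monthly noise scale, seasonal base, amplitude
_CLIMATE_PARAMS = {
    "temperature": dict(slope=0.012, noise=1.5, base=24.0, amplitude=4.0),
    "rainfall": dict(slope=1.2, noise=25.0, base=80.0, amplitude=60.0),
    "relative_humidity": dict(slope=0.06, noise=4.0, base=70.0,
                              amplitude=8.0),
}

# indicator -> (kind, intercept, loading); kind "pct" is 100*logistic,
# "exp" an exponential rate scale. Loadings are applied to the latent
# vulnerability z for sensitivity and to the capacity score c = -z (+
# capital boost) for adaptive capacity; negative loadings implement
# "higher is worse capacity" indicators such as inhabitants per facility.
_SENSITIVITY_PARAMS = {
    "cholera_outbreaks": ("exp", 0.0, 0.3),
    "food_insecurity": ("exp", 0.5, 0.25),
    "pop_density": ("exp", 3.5, 0.3),
    "pct_under5": ("pct", -1.6, 0.15),
    "pct_age5_15": ("pct", -1.0, 0.125),
    "pct_women": ("pct", 0.05, 0.05),
    "pct_over60": ("pct", -3.0, 0.15),
    "hiv_positivity": ("pct", -2.2, 0.20),
    "tb_rate": ("exp", 5.0, 0.25),
    "malnutrition_rate": ("exp", 6.0, 0.25),
    "malaria_rate": ("exp", 2.5, 0.3),
    "diarrhea_rate": ("exp", 7.0, 0.25),
}

# Capacity indicators are right-skewed on purpose: most districts sit at
# low access/coverage levels with provincial capitals outlying high, the
# pattern min-max normalization turns into low AC scores for the rural
# majority (and hence widespread positive E - AC, as real assessments of
# low-income settings find).
_ADAPTIVE_PARAMS = {
    "health_expenditure_pc": ("exp", 6.0, 0.72),
    "per_capita_expenditure": ("exp", 7.5, 0.72),      # province level
    "inhabitants_per_health_unit": ("exp", 9.0, -0.72),
    "pct_within_health_radius": ("pct", -0.2, 0.72),
    "medical_workers_per_100k": ("exp", 1.5, 0.84),
    "nursing_workers_per_100k": ("exp", 3.0, 0.72),
    "midwifery_workers_per_100k": ("exp", 2.0, 0.72),
    "inhabitants_per_ape": ("exp", 7.5, -0.72),
    "pct_safe_water": ("pct", -0.8, 0.84),
    "pct_safe_latrines": ("pct", -1.0, 0.84),
    "pct_literate_men": ("pct", 0.0, 0.72),
    "pct_primary_men": ("pct", -0.3, 0.72),
    "pct_secondary_men": ("pct", -2.0, 0.84),
    "pct_literate_women": ("pct", -0.6, 0.72),
    "pct_primary_women": ("pct", -0.7, 0.72),
    "pct_secondary_women": ("pct", -2.5, 0.84),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic panel generator.

    Defaults emulate the study conditions: 161 districts in 11 provinces,
    a 1980-2019 extreme-event window and a 1970-2016 monthly climate
    record. ``noise_sd`` is the indicator-level noise standard deviation
    in units of ``latent_sd``-scaled latent scores; climate monthly noise
    scales off the same knob per variable.
    """

    n_districts: int = 161
    n_provinces: int = 11
    seed: int = 7
    latent_sd: float = 1.0
    noise_sd: float = 0.3
    capital_ac_boost: float = 2.0
    missing_rate: float = 0.05
    province_level_indicators: tuple[str, ...] = ("per_capita_expenditure",)
    hazard_rates: Mapping[str, float] = field(
        default_factory=lambda: {"drought": 4.0, "flood": 5.0,
                                 "cyclone": 2.5})
    cyclone_coastal_multiplier: float = 3.0
    drought_south_multiplier: float = 2.5
    hazard_window: tuple[int, int] = (1980, 2019)
    climate_years: tuple[int, int] = (1970, 2016)
    province_effect_share: float = 0.6

    def __post_init__(self):
        if self.n_provinces > self.n_districts:
            raise ConfigError("n_provinces exceeds n_districts")
        if self.n_provinces < 1 or self.n_districts < 1:
            raise ConfigError("counts must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.latent_sd <= 0:
            raise ConfigError("latent_sd must be positive")
        if self.noise_sd < 0 or self.capital_ac_boost < 0:
            raise ConfigError("noise_sd and capital_ac_boost must be >= 0")
        if any(r < 0 for r in self.hazard_rates.values()):
            raise ConfigError("hazard rates must be >= 0")
        if set(self.hazard_rates) != set(HAZARDS):
            raise ConfigError(f"hazard_rates must cover {HAZARDS}")
        if self.climate_years[1] - self.climate_years[0] + 1 < 2:
            raise ConfigError("climate span must cover >= 2 years")
        if self.hazard_window[0] > self.hazard_window[1]:
            raise ConfigError("hazard_window start exceeds end")


@dataclass
class SyntheticPanel:
    """One generated panel; ``latent`` is truth held out for validation."""

    roster: list[District]
    table: pd.DataFrame
    province_values: pd.DataFrame
    monthly_climate: pd.DataFrame
    events: pd.DataFrame
    latent: pd.Series
    climate_slopes: pd.DataFrame
    spec: GeneratorSpec
    schema: Schema

    @property
    def roster_frame(self) -> pd.DataFrame:
        return roster_frame(self.roster)

    def to_dir(self, path: str | Path) -> None:
        """Write the panel as the delimited formats the pipeline reads."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.roster_frame.to_csv(path / "roster.csv")
        hio.write_indicator_table(self.table, path / "indicators.csv")
        hio.write_province_values(self.province_values,
                                  path / "province_values.csv")
        hio.write_monthly_climate(self.monthly_climate,
                                  path / "monthly_climate.csv")
        hio.write_events(self.events, path / "events.csv")
        self.latent.rename("latent").to_csv(path / "truth_latent.csv")
        self.climate_slopes.to_csv(path / "truth_climate_slopes.csv")


def _province_roster(spec: GeneratorSpec):
    provinces = list(PROVINCES[:spec.n_provinces])
    for k in range(len(provinces), spec.n_provinces):
        # beyond the packaged 11 (only reachable in stress tests)
        from .schema import Province
        provinces.append(Province(f"P{k+1:02d}", f"Province {k+1}",
                                  "centre", False))
    return provinces


def _build_roster(spec: GeneratorSpec, rng: np.random.Generator,
                  ) -> list[District]:
    provinces = _province_roster(spec)
    base, extra = divmod(spec.n_districts, spec.n_provinces)
    sizes = [base + (1 if i < extra else 0)
             for i in range(spec.n_provinces)]
    roster: list[District] = []
    k = 0
    for prov, size in zip(provinces, sizes):
        for j in range(size):
            k += 1
            capital = j == 0
            coastal = bool(prov.coastal and
                           (capital or rng.random() < 0.45))
            pop_mu = 12.5 if capital else 11.0
            population = int(np.exp(rng.normal(pop_mu, 0.4)))
            name = (f"{prov.name} City" if capital
                    else f"{prov.name} District {j}")
            roster.append(District(
                district_id=f"D{k:03d}", name=name,
                province_id=prov.province_id, is_capital=capital,
                population=population, coastal=coastal,
                region=prov.region))
    return roster


def _transform(kind: str, intercept: float, loading: float,
               score: np.ndarray) -> np.ndarray:
    lin = intercept + loading * score
    if kind == "pct":
        return 100.0 / (1.0 + np.exp(-lin))
    if kind == "exp":
        return np.exp(lin)
    raise ValueError(kind)


def generate_monthly_climate(spec: GeneratorSpec, district: District,
                             slopes: Mapping[str, float] | None = None,
                             rng: np.random.Generator | None = None,
                             ) -> pd.DataFrame:
    """Monthly temperature, rainfall and relative-humidity series for one
    district: seasonal sinusoid + linear trend + noise, in long form.

    ``slopes`` (units per year, keyed by variable) default to zero; pass
    the district's latent-linked slopes to reproduce the panel's series.
    """
    y0, y1 = spec.climate_years
    if y1 - y0 + 1 < 2:
        raise ConfigError("climate span must cover >= 2 years")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    slopes = dict(slopes or {})
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)
    yy, mm = np.meshgrid(years, months, indexing="ij")
    t = (yy - y0) + (mm - 0.5) / 12.0
    frames = []
    for var, p in _CLIMATE_PARAMS.items():
        seasonal = p["amplitude"] * np.cos(2 * np.pi * (mm - 1) / 12.0)
        trend = slopes.get(var, 0.0) * t
        noise = rng.normal(0.0, p["noise"] * spec.noise_sd, size=t.shape)
        values = p["base"] + seasonal + trend + noise
        frames.append(pd.DataFrame({
            "district_id": district.district_id, "variable": var,
            "year": yy.ravel(), "month": mm.ravel(),
            "value": values.ravel()}))
    return pd.concat(frames, ignore_index=True)


def generate(spec: GeneratorSpec | None = None,
             schema: Schema | None = None) -> SyntheticPanel:
    """Generate a full synthetic panel; a pure function of (spec, schema)."""
    spec = spec or GeneratorSpec()
    schema = schema or default_schema()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    roster = _build_roster(spec, rng)
    rdf = roster_frame(roster)
    idx = rdf.index
    n = len(idx)

    # latent vulnerability: regional gradient + province effect + district
    prov_ids = rdf["province_id"]
    unique_prov = prov_ids.unique()
    u_p = pd.Series(
        rng.normal(0.0, spec.province_effect_share * spec.latent_sd,
                   size=len(unique_prov)), index=unique_prov)
    region_off = rdf["region"].map(_REGION_OFFSET) * spec.latent_sd
    v = (region_off + prov_ids.map(u_p)
         + rng.normal(0.0, spec.latent_sd, size=n))
    v.name = "latent"

    noise = spec.noise_sd * spec.latent_sd

    table = pd.DataFrame(index=idx)
    prov_level = set(spec.province_level_indicators)
    for ind_id, (kind, b0, b1) in _SENSITIVITY_PARAMS.items():
        z = v.to_numpy() + rng.normal(0.0, noise, size=n)
        table[ind_id] = _transform(kind, b0, b1, z)
    capacity_base = (-v.to_numpy()
                     + spec.capital_ac_boost
                     * rdf["is_capital"].to_numpy(dtype=float))
    for ind_id, (kind, b0, b1) in _ADAPTIVE_PARAMS.items():
        if ind_id in prov_level:
            continue
        c = capacity_base + rng.normal(0.0, noise, size=n)
        table[ind_id] = _transform(kind, b0, b1, c)

    # province-level indicators from province-mean capacity
    prov_capacity = pd.Series(capacity_base, index=idx).groupby(
        prov_ids).mean()
    province_values = pd.DataFrame(index=pd.Index(unique_prov,
                                                  name="province_id"))
    for ind_id in sorted(prov_level):
        kind, b0, b1 = _ADAPTIVE_PARAMS[ind_id]
        c = (prov_capacity.to_numpy()
             + rng.normal(0.0, noise, size=len(prov_capacity)))
        province_values[ind_id] = _transform(kind, b0, b1, c)
        table[ind_id] = np.nan  # filled by province broadcast downstream

    # monthly climate: latent-linked trend slopes per variable
    slopes = pd.DataFrame(index=idx)
    for var, p in _CLIMATE_PARAMS.items():
        slopes[var] = p["slope"] * (
            v.to_numpy() + rng.normal(0.0, noise, size=n))
    climate_frames = []
    for i, d in enumerate(roster):
        climate_frames.append(generate_monthly_climate(
            spec, d, slopes=slopes.iloc[i].to_dict(), rng=rng))
    monthly_climate = pd.concat(climate_frames, ignore_index=True)

    # hazard events: Poisson counts with geographic multipliers
    lo, hi = spec.hazard_window
    records = []
    south = (rdf["region"] == "south").to_numpy()
    coastal = rdf["coastal"].to_numpy()
    for hazard in HAZARDS:
        rate = np.full(n, float(spec.hazard_rates[hazard]))
        if hazard == "cyclone":
            rate = np.where(coastal,
                            rate * spec.cyclone_coastal_multiplier, rate)
        if hazard == "drought":
            rate = np.where(south,
                            rate * spec.drought_south_multiplier, rate)
        counts = rng.poisson(rate)
        for did, cnt in zip(idx, counts):
            if cnt:
                years = rng.integers(lo, hi + 1, size=cnt)
                records.extend((did, hazard, int(yr)) for yr in years)
    events = pd.DataFrame(records,
                          columns=["district_id", "hazard", "year"])

    # sporadic missingness, capped at half of each province's districts
    if spec.missing_rate > 0:
        district_cols = [c for c in table.columns if c not in prov_level]
        by_prov = {p: np.flatnonzero((prov_ids == p).to_numpy())
                   for p in unique_prov}
        for col in district_cols:
            ci = table.columns.get_loc(col)
            for p, members in by_prov.items():
                k = int(rng.binomial(len(members), spec.missing_rate))
                k = min(k, len(members) // 2)
                if k:
                    hit = rng.choice(members, size=k, replace=False)
                    table.iloc[hit, ci] = np.nan

    return SyntheticPanel(
        roster=roster, table=table, province_values=province_values,
        monthly_climate=monthly_climate, events=events, latent=v,
        climate_slopes=slopes, spec=spec, schema=schema)


def load_panel_dir(path: str | Path,
                   schema: Schema | None = None) -> SyntheticPanel:
    """Reload a panel written by :meth:`SyntheticPanel.to_dir`."""
    path = Path(path)
    schema = schema or default_schema()
    rdf = pd.read_csv(path / "roster.csv").set_index("district_id")
    roster = [District(district_id=i, name=r["name"],
                       province_id=r["province_id"],
                       is_capital=bool(r["is_capital"]),
                       population=int(r["population"]),
                       coastal=bool(r["coastal"]), region=r["region"])
              for i, r in rdf.iterrows()]
    table = hio.read_indicator_table(path / "indicators.csv", schema,
                                     roster_ids=rdf.index)
    latent_path = path / "truth_latent.csv"
    if latent_path.exists():
        latent = pd.read_csv(latent_path).set_index("district_id")["latent"]
    else:
        latent = pd.Series(np.nan, index=table.index, name="latent")
    slopes_path = path / "truth_climate_slopes.csv"
    slopes = (pd.read_csv(slopes_path).set_index("district_id")
              if slopes_path.exists()
              else pd.DataFrame(index=table.index))
    return SyntheticPanel(
        roster=roster, table=table,
        province_values=hio.read_province_values(
            path / "province_values.csv"),
        monthly_climate=hio.read_monthly_climate(
            path / "monthly_climate.csv"),
        events=hio.read_events(path / "events.csv"),
        latent=latent, climate_slopes=slopes,
        spec=GeneratorSpec(), schema=schema)
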