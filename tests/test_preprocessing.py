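"""Climate variation, hazard counts, imputation and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import hvindex as hv
from hvindex.errors import HVIError
from hvindex.preprocessing import (climate_variation_table,
                                   hazard_frequency_table, impute_missing,
                                   min_max_normalize)
from hvindex.schema import roster_frame, District

from conftest import mini_schema


def monthly_frame(annual_means):
    rows = []
    for i, mean in enumerate(annual_means):
        for m in range(1, 13):
            rows.append({"year": 2000 + i, "month": m, "value": mean})
    return pd.DataFrame(rows)


class TestAnnualVariation:
    def test_constant_series_zero_both_methods(self):
        mf = monthly_frame([20.0] * 6)
        assert hv.annual_variation(mf, "trend_total_change") \
            == pytest.approx(0.0, abs=1e-12)
        assert hv.annual_variation(mf, "endpoint_difference") == 0.0

    def test_exact_linear_trend_closed_form(self):
        b, years = 0.7, 9
        mf = monthly_frame([10 + b * i for i in range(years)])
        assert hv.annual_variation(mf, "trend_total_change") \
            == pytest.approx(b * (years - 1), rel=1e-12)

    def test_two_year_endpoint_difference(self):
        mf = monthly_frame([20.0, 21.5])
        assert hv.annual_variation(mf, "endpoint_difference", k=1) \
            == pytest.approx(1.5)

    def test_linearity_in_deviations(self):
        rng = np.random.default_rng(0)
        means = 15 + rng.normal(0, 2, size=8)
        doubled = means.mean() + 2 * (means - means.mean())
        v1 = hv.annual_variation(monthly_frame(means))
        v2 = hv.annual_variation(monthly_frame(doubled))
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_incomplete_trailing_year_dropped_with_warning(self):
        mf = monthly_frame([20.0, 21.0, 22.0])
        mf = mf[~((mf["year"] == 2002) & (mf["month"] > 3))]
        with pytest.warns(UserWarning, match="incomplete"):
            v = hv.annual_variation(mf, "endpoint_difference", k=1)
        assert v == pytest.approx(1.0)

    def test_single_year_rejected(self):
        with pytest.raises(HVIError, match="2 complete years"):
            hv.annual_variation(monthly_frame([20.0]))

    def test_vectorized_table_matches_scalar_path(self, small_panel):
        table = climate_variation_table(small_panel.monthly_climate)
        clim = small_panel.monthly_climate
        for did in list(table.index)[:4]:
            one = clim[(clim["district_id"] == did)
                       & (clim["variable"] == "temperature")]
            assert table.loc[did, "temp_variation"] \
                == pytest.approx(hv.annual_variation(one), rel=1e-9)


class TestHazardFrequency:
    events = pd.DataFrame({
        "district_id": ["D1", "D1", "D1", "D1", "D2"],
        "hazard": ["flood", "flood", "flood", "flood", "flood"],
        "year": [1985, 1999, 2010, 1975, 1990],
    })

    def test_counts_in_window(self):
        assert hv.hazard_frequency(self.events, "D1", "flood",
                                   (1980, 2019)) == 3

    def test_other_district_ignored(self):
        assert hv.hazard_frequency(self.events, "D3", "flood",
                                   (1980, 2019)) == 0

    def test_empty_events(self):
        empty = self.events.iloc[:0]
        assert hv.hazard_frequency(empty, "D1", "flood", (1980, 2019)) == 0

    def test_table_combined_is_sum_of_hazards(self, default_panel):
        tab = hazard_frequency_table(default_panel.events,
                                     default_panel.roster_frame.index)
        per_hazard = tab[[f"hazard_freq_{h}" for h in hv.HAZARDS]]
        np.testing.assert_allclose(tab["extreme_event_freq"],
                                   per_hazard.sum(axis=1))


class TestImputation:
    def _roster(self):
        return roster_frame([
            District("D1", "a", "P01"), District("D2", "b", "P01"),
            District("D3", "c", "P01"), District("D4", "d", "P02"),
            District("D5", "e", "P02")])

    def test_province_mean_fills_sporadic_gap(self):
        sch = mini_schema(n_e=1, n_s=0, n_ac=0)
        table = pd.DataFrame({"e0": [0.2, 0.4, np.nan, 1.0, 2.0]},
                             index=["D1", "D2", "D3", "D4", "D5"])
        res = impute_missing(table, sch, self._roster())
        assert res.table.loc["D3", "e0"] == pytest.approx(0.3)
        assert res.flags.loc["D3", "e0"] == "province_mean"
        assert res.n_imputed == 1

    def test_province_value_broadcast(self):
        sch = mini_schema(n_e=0, n_s=0, n_ac=1, invert_last_ac=False)
        # promote the indicator to province level
        from hvindex.schema import (Schema, IndicatorDef, Component,
                                    SpatialLevel)
        sch = Schema([IndicatorDef("a0", "x", Component.ADAPTIVE_CAPACITY,
                                   "Financial resources",
                                   spatial_level=SpatialLevel.PROVINCE)])
        table = pd.DataFrame({"a0": [np.nan] * 5},
                             index=["D1", "D2", "D3", "D4", "D5"])
        pv = pd.DataFrame({"a0": [7.7, 3.3]}, index=["P01", "P02"])
        res = impute_missing(table, sch, self._roster(),
                             province_values=pv)
        assert (res.table.loc[["D1", "D2", "D3"], "a0"] == 7.7).all()
        assert (res.table.loc[["D4", "D5"], "a0"] == 3.3).all()
        assert (res.flags["a0"] == "province_broadcast").all()

    def test_complete_table_unchanged(self):
        sch = mini_schema(n_e=1, n_s=0, n_ac=0)
        table = pd.DataFrame({"e0": [1.0, 2, 3, 4, 5]},
                             index=["D1", "D2", "D3", "D4", "D5"])
        res = impute_missing(table, sch, self._roster())
        pd.testing.assert_frame_equal(res.table, table)
        assert res.n_imputed == 0

    def test_idempotence(self, small_panel):
        rdf = small_panel.roster_frame
        once = impute_missing(small_panel.table, small_panel.schema, rdf,
                              province_values=small_panel.province_values)
        twice = impute_missing(once.table, small_panel.schema, rdf,
                               province_values=small_panel.province_values)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_observed_cells_never_altered(self, small_panel):
        rdf = small_panel.roster_frame
        res = impute_missing(small_panel.table, small_panel.schema, rdf,
                             province_values=small_panel.province_values)
        observed = small_panel.table.notna()
        pd.testing.assert_frame_equal(res.table.where(observed),
                                      small_panel.table.where(observed))

    def test_province_mean_preserved_by_sporadic_rule(self):
        sch = mini_schema(n_e=1, n_s=0, n_ac=0)
        table = pd.DataFrame({"e0": [0.2, 0.4, np.nan, 1.0, np.nan]},
                             index=["D1", "D2", "D3", "D4", "D5"])
        res = impute_missing(table, sch, self._roster())
        assert res.table.loc[["D1", "D2", "D3"], "e0"].mean() \
            == pytest.approx(table.loc[["D1", "D2"], "e0"].mean())
        assert res.table.loc[["D4", "D5"], "e0"].mean() \
            == pytest.approx(1.0)

    def test_whole_province_gap_uses_national_mean_flagged(self):
        sch = mini_schema(n_e=1, n_s=0, n_ac=0)
        table = pd.DataFrame({"e0": [1.0, 2.0, 3.0, np.nan, np.nan]},
                             index=["D1", "D2", "D3", "D4", "D5"])
        res = impute_missing(table, sch, self._roster())
        assert res.table.loc["D4", "e0"] == pytest.approx(2.0)
        assert res.flags.loc["D4", "e0"] == "national_mean"
        assert res.national_fallback == ["e0"]

    def test_fully_unobserved_indicator_errors_by_name(self):
        sch = mini_schema(n_e=1, n_s=0, n_ac=0)
        table = pd.DataFrame({"e0": [np.nan] * 5},
                             index=["D1", "D2", "D3", "D4", "D5"])
        with pytest.raises(HVIError, match="e0"):
            impute_missing(table, sch, self._roster())


class TestMinMaxNormalize:
    def _one_col(self, values, **schema_kw):
        sch = mini_schema(n_e=1, n_s=0, n_ac=0, **schema_kw)
        table = pd.DataFrame({"e0": values},
                             index=[f"D{i}" for i in range(len(values))])
        return sch, table

    def test_basic_rescaling(self):
        sch, table = self._one_col([5.0, 10.0, 15.0])
        norm = min_max_normalize(table, sch)
        np.testing.assert_allclose(norm.data["e0"], [0.0, 0.5, 1.0])

    def test_reflection_for_inverse_indicators(self):
        sch = mini_schema(n_e=0, n_s=0, n_ac=1)  # a0 is higher_is_less
        table = pd.DataFrame({"a0": [5.0, 10.0, 15.0]},
                             index=["D0", "D1", "D2"])
        norm = min_max_normalize(table, sch)
        np.testing.assert_allclose(norm.data["a0"], [1.0, 0.5, 0.0])

    def test_degenerate_zero_fill(self):
        sch, table = self._one_col([7.0, 7.0, 7.0])
        with pytest.warns(UserWarning, match="degenerate"):
            norm = min_max_normalize(table, sch, "zero_fill")
        np.testing.assert_allclose(norm.data["e0"], [0.0, 0.0, 0.0])
        assert norm.records.loc["e0", "degenerate"]
        assert not norm.records.loc["e0", "dropped"]

    def test_degenerate_drop(self):
        sch, table = self._one_col([7.0, 7.0, 7.0])
        with pytest.warns(UserWarning):
            norm = min_max_normalize(table, sch, "drop_indicator")
        assert "e0" not in norm.data.columns
        assert norm.dropped == ["e0"]

    def test_missing_cells_rejected(self):
        sch, table = self._one_col([1.0, np.nan, 3.0])
        with pytest.raises(HVIError, match="missing"):
            min_max_normalize(table, sch)

    def test_nondegenerate_attains_both_bounds(self, small_result):
        norm = small_result.normalized
        live = ~norm.records["degenerate"]
        for col in norm.records.index[live]:
            assert norm.data[col].min() == 0.0
            assert norm.data[col].max() == 1.0

    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=12,
                    unique=True),
           st.floats(0.5, 100.0), st.floats(-1e3, 1e3))
    def test_affine_invariance(self, values, a, b):
        # integer base values keep a*X + b exactly distinct in floats
        sch, table = self._one_col([float(v) for v in values])
        base = min_max_normalize(table, sch).data["e0"]
        scaled = min_max_normalize(table * a + b, sch).data["e0"]
        np.testing.assert_allclose(scaled, base, atol=1e-9)
        assert base.between(0, 1).all()
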