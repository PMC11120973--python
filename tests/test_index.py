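"""Sub-index aggregation, the HVI equation, hazard-specific and
determinant indices, and the PCA cross-check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

import hvindex as hv
from hvindex.errors import HVIError
from hvindex.index import pca_index
from hvindex.preprocessing import min_max_normalize, NormalizedTable
from hvindex.schema import (Schema, IndicatorDef, Component, Direction,
                            CLIMATE_INDICATORS)

from conftest import (mini_schema, random_table, brute_force_hvi,
                      library_hvi, monotonicity_probes)


class TestWeightedSum:
    def test_equal_weights_are_the_mean(self):
        row = {"a": 0.2, "b": 0.4, "c": 0.6, "d": 0.8}
        w = {k: 0.25 for k in row}
        assert hv.weighted_sum(row, w) == pytest.approx(0.5)

    def test_degenerate_weight_selects_one(self):
        assert hv.weighted_sum({"a": 0.3, "b": 0.9, "c": 0.1},
                               {"a": 1.0, "b": 0.0, "c": 0.0}) \
            == pytest.approx(0.3)

    def test_all_zero_row(self):
        assert hv.weighted_sum({"a": 0.0, "b": 0.0},
                               {"a": 0.5, "b": 0.5}) == 0.0

    def test_key_mismatch_rejected(self):
        with pytest.raises(HVIError, match="keys"):
            hv.weighted_sum({"a": 1.0}, {"b": 1.0})

    def test_bad_weight_sum_rejected(self):
        with pytest.raises(HVIError, match="sum"):
            hv.weighted_sum({"a": 1.0, "b": 0.0}, {"a": 0.7, "b": 0.2})


def make_norm(schema, data):
    """Wrap a ready [0,1] matrix as a NormalizedTable."""
    records = pd.DataFrame(
        {"x_min": 0.0, "x_max": 1.0,
         "direction": [schema[c].direction.value for c in data.columns],
         "degenerate": False, "dropped": False},
        index=pd.Index(data.columns, name="indicator_id"))
    return NormalizedTable(data=data, records=records, schema=schema)


class TestSubIndices:
    def test_unit_and_zero_endpoints(self):
        sch = mini_schema(2, 2, 2, invert_last_ac=False)
        ones = pd.DataFrame(1.0, index=["D1"], columns=sch.ids)
        zeros = pd.DataFrame(0.0, index=["D1"], columns=sch.ids)
        s1 = hv.compute_subindices(make_norm(sch, ones))
        s0 = hv.compute_subindices(make_norm(sch, zeros))
        assert (s1.loc["D1"] == 1.0).all()
        assert (s0.loc["D1"] == 0.0).all()

    def test_exposure_mean_of_four(self):
        sch = mini_schema(4, 1, 1, invert_last_ac=False)
        data = pd.DataFrame(
            [[0.0, 0.0, 1.0, 1.0, 0.5, 0.5]], index=["D1"],
            columns=sch.ids)
        sub = hv.compute_subindices(make_norm(sch, data))
        assert sub.loc["D1", "E"] == pytest.approx(0.5)


class TestHVIEquation:
    @pytest.mark.parametrize("e,ac,s,expected", [
        (1.0, 0.0, 1.0, 1.0),
        (0.4, 0.4, 0.7, 0.0),
        (0.9, 0.1, 0.0, 0.0),
        (0.6, 0.2, 0.5, 0.2),
    ])
    def test_direct_arithmetic(self, e, ac, s, expected):
        sub = pd.DataFrame({"E": [e], "S": [s], "AC": [ac]}, index=["D1"])
        assert hv.compute_hvi(sub).loc["D1"] == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_bounds_and_sign(self, e, s, ac):
        sub = pd.DataFrame({"E": [e], "S": [s], "AC": [ac]}, index=["D1"])
        hvi = float(hv.compute_hvi(sub).loc["D1"])
        assert -1.0 <= hvi <= 1.0
        assert (hvi > 0) == (e > ac and s > 0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,n_districts", [(1, 4), (2, 6), (3, 5)])
    def test_pipeline_matches_brute_force(self, seed, n_districts):
        sch = mini_schema(2, 2, 2)
        table = random_table(sch, n_districts,
                             np.random.default_rng(seed))
        lib = library_hvi(table, sch)
        oracle = brute_force_hvi(table, sch)
        for d in table.index:
            for key in ("E", "S", "AC", "HVI"):
                assert lib.loc[d, key] == pytest.approx(
                    oracle[d][key], abs=1e-12)

    def test_permutation_invariance(self):
        sch = mini_schema(2, 2, 2)
        table = random_table(sch, 6, np.random.default_rng(7))
        shuffled = table.sample(frac=1.0, random_state=1)
        a = library_hvi(table, sch)
        b = library_hvi(shuffled, sch)
        pd.testing.assert_frame_equal(a.loc[table.index],
                                      b.loc[table.index])


class TestMonotonicity:
    def test_finite_difference_probes(self):
        sch = mini_schema(2, 2, 2)
        rng = np.random.default_rng(21)
        table = random_table(sch, 10, rng)
        checked = monotonicity_probes(sch, table, rng, n_probes=60)
        assert checked >= 30


class TestHazardSpecific:
    def test_zero_count_district_composition(self, small_result,
                                             small_panel):
        # a district with zero events of a hazard has normalized term 0,
        # so its hazard exposure is 3/4 of its mean climate term
        norm = small_result.normalized
        for hazard in hv.HAZARDS:
            col = f"hazard_freq_{hazard}"
            zero = norm.data.index[norm.data[col] == 0.0]
            if zero.empty:
                continue
            d = zero[0]
            climate_mean = norm.data.loc[d, list(CLIMATE_INDICATORS)].mean()
            hvi_h = hv.hazard_specific_hvi(norm, hazard=hazard)
            e_h = climate_mean * 3 / 4
            s = small_result.subindices.loc[d, "S"]
            ac = small_result.subindices.loc[d, "AC"]
            assert hvi_h.loc[d] == pytest.approx((e_h - ac) * s, rel=1e-9)
            return
        pytest.skip("no zero-count district in panel")

    def test_monotone_in_event_count(self, small_panel):
        # brute force over a grid of added events for one district
        from hvindex.preprocessing import hazard_frequency_table
        cfg = hv.AssessmentConfig(seed=11)
        target = small_panel.table.index[0]
        values = []
        for extra in range(0, 6):
            events = pd.concat([small_panel.events, pd.DataFrame({
                "district_id": [target] * extra,
                "hazard": ["flood"] * extra,
                "year": [2000] * extra})], ignore_index=True)
            import dataclasses
            panel = dataclasses.replace(small_panel, events=events)
            res = hv.run_pipeline(cfg, panel=panel)
            values.append(res.results.loc[target, "hvi_flood"])
        diffs = np.diff(values)
        assert (diffs >= -1e-12).all()

    def test_unknown_hazard_rejected(self, small_result):
        with pytest.raises(HVIError, match="hazard"):
            hv.hazard_specific_hvi(small_result.normalized,
                                   hazard="earthquake")


class TestDeterminantSubindex:
    def test_group_of_one_equals_indicator(self):
        sch = mini_schema(1, 1, 1, invert_last_ac=False)
        data = pd.DataFrame([[0.2, 0.5, 0.8]], index=["D1"],
                            columns=sch.ids)
        norm = make_norm(sch, data)
        out = hv.determinant_subindex(norm, determinant="Health services")
        assert out.loc["D1"] == pytest.approx(0.8)

    def test_mean_of_two(self):
        sch = mini_schema(1, 1, 2, invert_last_ac=False)
        data = pd.DataFrame([[0.0, 0.0, 0.1, 0.3]], index=["D1"],
                            columns=sch.ids)
        out = hv.determinant_subindex(make_norm(sch, data),
                                      determinant="Health services")
        assert out.loc["D1"] == pytest.approx(0.2)

    def test_unknown_label_lists_valid(self, small_result):
        with pytest.raises(HVIError, match="Water and sanitation"):
            hv.determinant_subindex(small_result.normalized,
                                    determinant="Nope")

    def test_bounded(self, small_result):
        for det in ("Health services", "Human resources",
                    "Water and sanitation", "Financial resources"):
            out = hv.determinant_subindex(small_result.normalized,
                                          determinant=det)
            assert out.between(0, 1).all()


class TestPCAIndex:
    def test_rank_one_matrix_explains_everything(self):
        sch = mini_schema(2, 0, 0)
        x = np.linspace(0, 1, 8)
        data = pd.DataFrame({"e0": x, "e1": 1 - (1 - x) ** 1},
                            index=[f"D{i}" for i in range(8)])
        rep = pca_index(make_norm(sch, data))
        assert rep.explained_variance_share == pytest.approx(1.0)

    def test_duplication_leaves_ranking_unchanged(self):
        sch = mini_schema(2, 2, 2)
        table = random_table(sch, 8, np.random.default_rng(3))
        norm = min_max_normalize(table, sch)
        rep1 = pca_index(norm)
        doubled = pd.concat([table, table.set_axis(
            [f"X{i}" for i in range(len(table))])])
        norm2 = min_max_normalize(doubled, sch)
        rep2 = pca_index(norm2)
        first_half = rep2.scores.iloc[:len(table)]
        assert spearmanr(rep1.scores, first_half)[0] == pytest.approx(1.0)

    def test_zero_variance_matrix_rejected(self):
        sch = mini_schema(2, 0, 0)
        data = pd.DataFrame(0.5, index=["D1", "D2", "D3"],
                            columns=sch.ids)
        with pytest.raises(HVIError, match="variance"):
            pca_index(make_norm(sch, data))

    def test_orientation_positive_on_exposure(self, small_result):
        rep = small_result.pca
        exp_ids = [c for c in
                   small_result.normalized.schema.component_ids("exposure")
                   if c in rep.loadings.index]
        assert rep.loadings[exp_ids].mean() > 0
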