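"""Shared fixtures and independent oracles.

``brute_force_hvi`` recomputes the whole normalize -> sub-index -> HVI
chain with plain Python loops, independently of the library's vectorized
path, for oracle-equivalence checks on tiny tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import hvindex as hv
from hvindex.schema import (IndicatorDef, Schema, Component, Direction,
                            SpatialLevel)

settings.register_profile(
    "suite", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schema():
    return hv.default_schema()


@pytest.fixture(scope="session")
def small_spec():
    # 30 districts / 5 provinces / 20 climate years: same structure as the
    # default panel at a fraction of the cost
    return hv.GeneratorSpec(n_districts=30, n_provinces=5, seed=11,
                            climate_years=(1997, 2016))


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return hv.generate(small_spec)


@pytest.fixture(scope="session")
def small_result(small_panel):
    return hv.run_pipeline(hv.AssessmentConfig(seed=11), panel=small_panel)


@pytest.fixture(scope="session")
def default_panel():
    return hv.generate(hv.GeneratorSpec())


@pytest.fixture(scope="session")
def default_result(default_panel):
    return hv.run_pipeline(hv.AssessmentConfig(), panel=default_panel)


# ---------------------------------------------------------------------------
# Toy schemas and tables
# ---------------------------------------------------------------------------

def mini_schema(n_e: int = 2, n_s: int = 2, n_ac: int = 2,
                invert_last_ac: bool = True) -> Schema:
    """A tiny schema with a configurable component split; the last
    adaptive-capacity indicator is higher_is_less when requested."""
    inds = []
    for k in range(n_e):
        inds.append(IndicatorDef(f"e{k}", f"exposure {k}",
                                 Component.EXPOSURE, "Extreme events"))
    for k in range(n_s):
        inds.append(IndicatorDef(f"s{k}", f"sensitivity {k}",
                                 Component.SENSITIVITY, "Demography"))
    for k in range(n_ac):
        direction = (Direction.HIGHER_IS_LESS
                     if invert_last_ac and k == n_ac - 1
                     else Direction.HIGHER_IS_MORE)
        inds.append(IndicatorDef(f"a{k}", f"capacity {k}",
                                 Component.ADAPTIVE_CAPACITY,
                                 "Health services", direction))
    return Schema(inds)


def random_table(schema: Schema, n_districts: int,
                 rng: np.random.Generator) -> pd.DataFrame:
    idx = pd.Index([f"D{i:03d}" for i in range(1, n_districts + 1)],
                   name="district_id")
    data = rng.normal(10.0, 5.0, size=(n_districts, len(schema.ids)))
    return pd.DataFrame(data, index=idx, columns=schema.ids)


# ---------------------------------------------------------------------------
# Brute-force oracle (plain loops, no shared code with the library path)
# ---------------------------------------------------------------------------

def brute_force_hvi(table: pd.DataFrame, schema: Schema) -> dict[str, dict]:
    """Straight-line recomputation: min-max per indicator (with
    reflection), equal-weight component means, HVI = (E - AC) * S."""
    norm: dict[str, dict[str, float]] = {}
    for col in table.columns:
        values = [float(table.loc[d, col]) for d in table.index]
        lo, hi = min(values), max(values)
        out = {}
        for d in table.index:
            x = float(table.loc[d, col])
            y = 0.0 if hi == lo else (x - lo) / (hi - lo)
            if schema[col].direction is Direction.HIGHER_IS_LESS:
                y = 1.0 - y
            if hi == lo:
                y = 0.0
            out[d] = y
        norm[col] = out
    result = {}
    comp_ids = {c: schema.component_ids(c) for c in Component}
    for d in table.index:
        means = {}
        for comp, ids in comp_ids.items():
            total = 0.0
            for i in ids:
                total += norm[i][d]
            means[comp] = total / len(ids)
        e = means[Component.EXPOSURE]
        s = means[Component.SENSITIVITY]
        ac = means[Component.ADAPTIVE_CAPACITY]
        result[d] = {"E": e, "S": s, "AC": ac, "HVI": (e - ac) * s}
    return result


def library_hvi(table: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """The library path the oracle is compared against."""
    norm = hv.min_max_normalize(table, schema)
    sub = hv.compute_subindices(norm, schema)
    sub["HVI"] = hv.compute_hvi(sub)
    return sub


def monotonicity_probes(schema: Schema, table: pd.DataFrame,
                        rng: np.random.Generator, n_probes: int = 40,
                        eps: float = 1e-4) -> int:
    """Finite-difference probes of HVI monotonicity on one table.

    Bumps single cells strictly inside their indicator's range so the
    min-max bounds are untouched, and checks the sign of the HVI change:
    nondecreasing for exposure/sensitivity bumps (the sensitivity case
    conditioned on E >= AC), nonincreasing for adaptive-capacity bumps.
    Returns the number of probes actually evaluated.
    """
    base = library_hvi(table, schema)
    checked = 0
    cols = list(table.columns)
    for _ in range(n_probes):
        col = cols[rng.integers(len(cols))]
        ind = schema[col]
        x = table[col]
        inner = x[(x > x.min()) & (x < x.max())]
        if inner.empty:
            continue
        d = inner.index[rng.integers(len(inner))]
        span = x.max() - x.min()
        delta = eps * span
        if float(x.loc[d]) + delta >= x.max():
            delta = -delta
        bumped = table.copy()
        bumped.loc[d, col] = x.loc[d] + delta
        new = library_hvi(bumped, schema)
        dh = new.loc[d, "HVI"] - base.loc[d, "HVI"]
        # effect direction of a raw increase, in vulnerability terms
        sign = 1.0 if delta > 0 else -1.0
        if ind.direction is Direction.HIGHER_IS_LESS:
            sign = -sign
        if ind.component is Component.ADAPTIVE_CAPACITY:
            # more capacity -> HVI must not increase
            assert sign * dh <= 1e-12, (col, d, dh)
        elif ind.component is Component.SENSITIVITY:
            if base.loc[d, "E"] >= base.loc[d, "AC"]:
                assert sign * dh >= -1e-12, (col, d, dh)
            else:
                continue
        else:
            assert sign * dh >= -1e-12, (col, d, dh)
        checked += 1
    return checked
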