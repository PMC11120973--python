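"""Sub-indices and the Health Vulnerability Index.

Given a complete normalized indicator matrix, each component sub-index is
a weighted sum of its indicators (equal weights by default — the
arithmetic mean), and the composite is

    HVI = (E - AC) x S

with E exposure, S sensitivity and AC adaptive capacity, all in [0, 1],
so HVI lies in [-1, 1]: positive when exposure outruns capacity, damped
by low sensitivity.

Also here: hazard-specific HVIs (exposure recomputed from the three
climate-variation indicators plus a single hazard's event frequency),
determinant sub-indices (thematic means within a component, e.g. water
and sanitation), and a principal-component cross-check index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .config import AssessmentConfig, WEIGHT_TOL
from .errors import HVIError
from .preprocessing import NormalizedTable
from .schema import (Schema, Component, HAZARDS, hazard_freq_column,
                     CLIMATE_INDICATORS)

__all__ = [
    "weighted_sum", "compute_subindices", "compute_hvi",
    "hazard_specific_hvi", "determinant_subindex",
    "pca_index", "PCAComparison",
]


def weighted_sum(row: Mapping[str, float], weights: Mapping[str, float],
                 ) -> float:
    """Sum of w_i * y_i over matching keys.

    Weights must be nonnegative and sum to 1 (tolerance 1e-9); with equal
    weights this is the arithmetic mean.
    """
    if set(row) != set(weights):
        raise HVIError(
            f"weight keys {sorted(weights)} do not match row keys "
            f"{sorted(row)}")
    if any(w < 0 for w in weights.values()):
        raise HVIError("negative weight")
    total = sum(weights.values())
    if abs(total - 1.0) > WEIGHT_TOL:
        raise HVIError(f"weights sum to {total!r}, expected 1.0")
    return float(sum(weights[k] * row[k] for k in row))


def _component_scores(norm: NormalizedTable, schema: Schema,
                      config: AssessmentConfig,
                      component: Component) -> pd.Series:
    ids = norm.surviving(schema.component_ids(component))
    if not ids:
        raise HVIError(
            f"component {component.value!r} has no surviving indicators "
            "(all dropped as degenerate)")
    weights = config.component_weights(schema, component, ids)
    w = np.array([weights[i] for i in ids])
    return pd.Series(norm.data[ids].to_numpy() @ w, index=norm.data.index)


def compute_subindices(norm: NormalizedTable,
                       schema: Schema | None = None,
                       config: AssessmentConfig | None = None,
                       ) -> pd.DataFrame:
    """Per-district E, S, AC, each a weighted sum of its component's
    normalized indicators (weights renormalized over survivors when
    degenerate indicators were dropped)."""
    schema = schema or norm.schema
    config = config or AssessmentConfig()
    return pd.DataFrame({
        "E": _component_scores(norm, schema, config, Component.EXPOSURE),
        "S": _component_scores(norm, schema, config, Component.SENSITIVITY),
        "AC": _component_scores(norm, schema, config,
                                Component.ADAPTIVE_CAPACITY),
    })


def compute_hvi(subindices: pd.DataFrame) -> pd.Series:
    """HVI = (E - AC) x S, per district."""
    hvi = (subindices["E"] - subindices["AC"]) * subindices["S"]
    hvi.name = "HVI"
    return hvi


def hazard_specific_hvi(norm: NormalizedTable,
                        schema: Schema | None = None,
                        config: AssessmentConfig | None = None,
                        hazard: str = "drought") -> pd.Series:
    """HVI recomputed with hazard-specific exposure.

    Exposure uses the three climate-variation indicators plus the selected
    hazard's own frequency column, equally weighted; sensitivity and
    adaptive capacity are unchanged.
    """
    if hazard not in HAZARDS:
        raise HVIError(f"unknown hazard {hazard!r}; expected one of "
                       f"{HAZARDS}")
    schema = schema or norm.schema
    config = config or AssessmentConfig()
    freq_col = hazard_freq_column(hazard)
    wanted = list(CLIMATE_INDICATORS) + [freq_col]
    present = [c for c in wanted
               if c in norm.data.columns or c in norm.records.index]
    missing = set(wanted) - set(present)
    if missing:
        raise HVIError(
            f"hazard-specific exposure needs columns {sorted(missing)}; "
            "normalize a table containing the per-hazard frequency columns")
    ids = norm.surviving(wanted)
    if not ids:
        raise HVIError("all hazard-exposure indicators degenerate/dropped")
    w = 1.0 / len(ids)
    e_h = pd.Series(norm.data[ids].to_numpy() @ np.full(len(ids), w),
                    index=norm.data.index)
    s = _component_scores(norm, schema, config, Component.SENSITIVITY)
    ac = _component_scores(norm, schema, config,
                           Component.ADAPTIVE_CAPACITY)
    hvi = (e_h - ac) * s
    hvi.name = f"HVI_{hazard}"
    return hvi


def determinant_subindex(norm: NormalizedTable,
                         schema: Schema | None = None,
                         determinant: str = "Water and sanitation",
                         ) -> pd.Series:
    """Equal-weight mean of the normalized indicators in one determinant
    group (e.g. health services access, human resources, WASH)."""
    schema = schema or norm.schema
    ids = schema.determinant_ids(determinant)
    if not ids:
        raise HVIError(
            f"unknown determinant {determinant!r}; valid labels: "
            f"{schema.determinants()}")
    ids = norm.surviving(ids)
    if not ids:
        raise HVIError(
            f"determinant {determinant!r} has no surviving indicators")
    out = norm.data[ids].mean(axis=1)
    out.name = determinant
    return out


@dataclass
class PCAComparison:
    """First-principal-component index and its agreement with the HVI."""

    scores: pd.Series
    explained_variance_share: float
    loadings: pd.Series
    dropped_columns: list[str]
    pearson: float | None = None
    spearman: float | None = None
    class_confusion: pd.DataFrame | None = None


def pca_index(norm: NormalizedTable, schema: Schema | None = None,
              hvi: pd.Series | None = None) -> PCAComparison:
    """First principal component of the pooled indicator matrix as an
    alternative vulnerability index.

    Adaptive-capacity columns are reflected (1 - Y) so every column points
    toward vulnerability; columns are standardized (correlation-matrix
    convention) and zero-variance columns dropped. The component is
    sign-oriented so the mean loading of the exposure indicators is
    positive. When ``hvi`` is given, the report carries Pearson and
    Spearman correlations and a quintile-class confusion matrix.
    """
    schema = schema or norm.schema
    ids = norm.surviving(schema.ids)
    if len(ids) < 2 or len(norm.data.index) < 2:
        raise HVIError("PCA needs at least 2 districts and 2 indicators")
    X = norm.data[ids].copy()
    ac_ids = set(schema.component_ids(Component.ADAPTIVE_CAPACITY))
    for col in X.columns:
        if col in ac_ids:
            X[col] = 1.0 - X[col]
    sd = X.to_numpy().std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    if not keep.any():
        raise HVIError("all indicator columns have zero variance; "
                       "PCA is undefined")
    cols = [c for c, k in zip(X.columns, keep) if k]
    Z = (X[cols].to_numpy() - X[cols].to_numpy().mean(axis=0)) / sd[keep]
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pd.Series(pca.components_[0], index=cols)
    exp_ids = [c for c in schema.component_ids(Component.EXPOSURE)
               if c in loadings.index]
    orient_pool = exp_ids or cols
    if loadings[orient_pool].mean() < 0:
        scores, loadings = -scores, -loadings
    scores = pd.Series(scores, index=norm.data.index, name="pca_index")
    report = PCAComparison(
        scores=scores,
        explained_variance_share=float(pca.explained_variance_ratio_[0]),
        loadings=loadings, dropped_columns=dropped)
    if hvi is not None:
        hvi = hvi.reindex(scores.index)
        report.pearson = float(stats.pearsonr(scores, hvi)[0])
        report.spearman = float(stats.spearmanr(scores, hvi)[0])
        from .classify import classify_quintiles
        if len(scores) >= 5:
            c_pca = classify_quintiles(scores).classes
            c_hvi = classify_quintiles(hvi).classes
            report.class_confusion = pd.crosstab(
                c_hvi.rename("hvi_class"), c_pca.rename("pca_class"))
    return report
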