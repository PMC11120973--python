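"""End-to-end assessment: preprocess -> sub-indices -> HVI ->
hazard-specific HVIs -> determinant sub-indices -> classification.

``run_pipeline`` consumes either a :class:`~hvindex.synthetic.SyntheticPanel`
or a directory of the delimited input files, and returns every
intermediate plus a run manifest (config echo, imputation and degeneracy
flags, per-stage log) suitable for JSON serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as hio
from .classify import classify_quintiles, exclude_extremes, EXCLUDED
from .config import AssessmentConfig
from .errors import HVIError, PipelineError
from .index import (compute_subindices, compute_hvi, hazard_specific_hvi,
                    determinant_subindex, pca_index, PCAComparison)
from .preprocessing import (climate_variation_table, hazard_frequency_table,
                            impute_missing, min_max_normalize,
                            NormalizedTable)
from .schema import Schema, default_schema, HAZARDS
from .synthetic import SyntheticPanel, load_panel_dir

__all__ = ["run_pipeline", "AssessmentResult",
           "DEFAULT_DETERMINANTS"]

logger = logging.getLogger("hvindex")

#: determinant sub-indices reported by default (adaptive-capacity themes)
DEFAULT_DETERMINANTS = ("Health services", "Human resources",
                        "Water and sanitation", "Financial resources")


@dataclass
class AssessmentResult:
    """Everything one assessment run produces."""

    results: pd.DataFrame          # per-district scores and classes
    normalized: NormalizedTable
    subindices: pd.DataFrame
    pca: PCAComparison
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        import json
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_results(self.results, outdir / "results.csv")
        hio.write_indicator_table(self.normalized.data,
                                  outdir / "normalized.csv")
        self.normalized.records.to_csv(outdir / "normalization_records.csv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except HVIError as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: AssessmentConfig | None = None,
                 panel: SyntheticPanel | str | Path | None = None,
                 schema: Schema | None = None) -> AssessmentResult:
    """Run the full assessment.

    ``panel`` is a SyntheticPanel, a directory of input files, or None
    (generate the default synthetic panel seeded from the config).
    """
    config = config or AssessmentConfig()
    if panel is None:
        from .synthetic import generate, GeneratorSpec
        panel = generate(GeneratorSpec(seed=config.seed))
    elif isinstance(panel, (str, Path)):
        panel = load_panel_dir(panel, schema=schema)
    schema = schema or panel.schema or default_schema()
    rdf = panel.roster_frame
    log: list[str] = []

    @_stage("preprocess")
    def _preprocess():
        climate = climate_variation_table(
            panel.monthly_climate, method=config.variation_method,
            k=config.endpoint_k)
        hazards = hazard_frequency_table(
            panel.events, rdf.index, window=config.hazard_window)
        raw = panel.table.join(climate, how="left").join(hazards,
                                                         how="left")
        imput = impute_missing(raw, schema, rdf,
                               policy=config.imputation_policy,
                               province_values=panel.province_values)
        log.append(f"imputed {imput.n_imputed} cells"
                   + (f"; national fallback for "
                      f"{imput.national_fallback}"
                      if imput.national_fallback else ""))
        norm = min_max_normalize(imput.table, schema,
                                 degenerate_policy=config.degenerate_policy)
        if norm.records["degenerate"].any():
            log.append("degenerate indicators: "
                       f"{list(norm.records.index[norm.records['degenerate']])}")
        return norm, imput

    norm, imput = _preprocess()

    @_stage("subindices")
    def _sub():
        sub = compute_subindices(norm, schema, config)
        return sub

    sub = _sub()

    @_stage("hvi")
    def _hvi():
        return compute_hvi(sub)

    hvi = _hvi()

    @_stage("hazard_specific")
    def _hazards():
        return {h: hazard_specific_hvi(norm, schema, config, h)
                for h in HAZARDS}

    hazard_hvis = _hazards()

    @_stage("determinants")
    def _dets():
        return {d: determinant_subindex(norm, schema, d)
                for d in DEFAULT_DETERMINANTS}

    determinants = _dets()

    @_stage("classification")
    def _classify():
        results = pd.DataFrame({
            "province_id": rdf["province_id"], "E": sub["E"],
            "S": sub["S"], "AC": sub["AC"], "HVI": hvi})
        for col in ("E", "S", "AC", "HVI"):
            results[f"{col.lower()}_class" if col != "HVI"
                    else "hvi_class"] = classify_quintiles(
                results[col], config.quantile_rule).classes
        exclusion = config.exclusion_list
        if exclusion is None:
            exclusion = tuple(rdf.index[rdf["is_capital"]])
        if exclusion:
            results["hvi_class_excl"] = exclude_extremes(
                results["HVI"], exclusion, config.quantile_rule).classes
        for h, series in hazard_hvis.items():
            results[f"hvi_{h}"] = series
            results[f"hvi_{h}_class"] = classify_quintiles(
                series, config.quantile_rule).classes
        for d, series in determinants.items():
            col = "det_" + d.lower().replace(" ", "_")
            results[col] = series
        return results, exclusion

    results, exclusion = _classify()

    @_stage("pca_crosscheck")
    def _pca():
        return pca_index(norm, schema, hvi=hvi)

    pca = _pca()
    log.append(f"pca explained variance "
               f"{pca.explained_variance_share:.3f}, spearman vs HVI "
               f"{pca.spearman:.3f}")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_districts": int(len(results)),
        "n_provinces": int(rdf["province_id"].nunique()),
        "exclusion_list": list(exclusion),
        "n_imputed_cells": imput.n_imputed,
        "national_fallback_indicators": imput.national_fallback,
        "degenerate_indicators":
            list(norm.records.index[norm.records["degenerate"]]),
        "dropped_indicators": norm.dropped,
        "quantile_rule": config.quantile_rule,
        "pca_explained_variance": pca.explained_variance_share,
        "pca_spearman_vs_hvi": pca.spearman,
        "pca_pearson_vs_hvi": pca.pearson,
        "stages": log,
    }
    return AssessmentResult(results=results, normalized=norm,
                            subindices=sub, pca=pca, manifest=manifest)
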