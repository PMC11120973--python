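"""Assessment configuration.

Holds everything a run needs beyond the data itself: indicator weights
(default equal within each component, i.e. arithmetic-mean aggregation),
the empirical quantile estimator for quintile breaks, imputation and
degenerate-indicator policies, the extreme-value exclusion list, the
hazard-count window and the climate-variation method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError
from .schema import Schema, Component

WEIGHT_TOL = 1e-9

_VALID_DEGENERATE = ("zero_fill", "drop_indicator")
_VALID_VARIATION = ("trend_total_change", "endpoint_difference")
_IMPUTATION_LEVELS = ("province_broadcast", "province_mean", "national_mean")


@dataclass
class AssessmentConfig:
    """Configuration for one vulnerability assessment run.

    ``weights`` maps component name -> {indicator_id: weight}; ``None``
    means equal weights (the arithmetic mean) for every component. Each
    component's weights must be nonnegative and sum to 1 within 1e-9.
    """

    weights: dict[str, dict[str, float]] | None = None
    quantile_rule: str = "linear"
    degenerate_policy: str = "zero_fill"
    imputation_policy: tuple[str, ...] = _IMPUTATION_LEVELS
    exclusion_list: tuple[str, ...] | None = None   # None -> capitals
    hazard_window: tuple[int, int] = (1980, 2019)
    variation_method: str = "trend_total_change"
    endpoint_k: int = 10
    seed: int = 7

    def __post_init__(self):
        if self.degenerate_policy not in _VALID_DEGENERATE:
            raise ConfigError(
                f"degenerate_policy must be one of {_VALID_DEGENERATE}, "
                f"got {self.degenerate_policy!r}")
        if self.variation_method not in _VALID_VARIATION:
            raise ConfigError(
                f"variation_method must be one of {_VALID_VARIATION}, "
                f"got {self.variation_method!r}")
        unknown = set(self.imputation_policy) - set(_IMPUTATION_LEVELS)
        if unknown:
            raise ConfigError(
                f"unknown imputation levels: {sorted(unknown)}")
        self.hazard_window = (int(self.hazard_window[0]),
                              int(self.hazard_window[1]))
        if self.hazard_window[0] > self.hazard_window[1]:
            raise ConfigError(
                f"hazard_window start {self.hazard_window[0]} exceeds end "
                f"{self.hazard_window[1]}")
        if self.endpoint_k < 1:
            raise ConfigError("endpoint_k must be >= 1")
        if self.weights is not None:
            for comp, wmap in self.weights.items():
                Component(comp)  # raises ValueError on bad name
                if any(w < 0 for w in wmap.values()):
                    raise ConfigError(
                        f"negative weight in component {comp!r}")
                total = sum(wmap.values())
                if abs(total - 1.0) > WEIGHT_TOL:
                    raise ConfigError(
                        f"weights for component {comp!r} sum to {total!r}, "
                        f"expected 1.0")

    # -- weight resolution -------------------------------------------------

    def component_weights(self, schema: Schema,
                          component: Component | str,
                          ids: Sequence[str] | None = None,
                          ) -> dict[str, float]:
        """Resolved weights for ``component`` restricted to ``ids``.

        ``ids`` defaults to the component's schema indicators. When a
        restriction removes indicators (degenerate drop), the remaining
        weights are renormalized to sum to 1.
        """
        component = Component(component)
        if ids is None:
            ids = schema.component_ids(component)
        ids = list(ids)
        if not ids:
            raise ConfigError(
                f"component {component.value!r} has no indicators left")
        if self.weights is None or component.value not in self.weights:
            w = 1.0 / len(ids)
            return {i: w for i in ids}
        wmap = self.weights[component.value]
        missing = [i for i in ids if i not in wmap]
        if missing:
            raise ConfigError(
                f"weights for component {component.value!r} missing "
                f"indicators {missing}")
        sub = {i: wmap[i] for i in ids}
        total = sum(sub.values())
        if total <= 0:
            raise ConfigError(
                f"weights for component {component.value!r} restricted to "
                f"{ids} sum to zero")
        return {i: w / total for i, w in sub.items()}

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["imputation_policy"] = list(self.imputation_policy)
        d["hazard_window"] = list(self.hazard_window)
        d["exclusion_list"] = (None if self.exclusion_list is None
                               else list(self.exclusion_list))
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssessmentConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "imputation_policy" in d and d["imputation_policy"] is not None:
            d["imputation_policy"] = tuple(d["imputation_policy"])
        if "hazard_window" in d and d["hazard_window"] is not None:
            d["hazard_window"] = tuple(d["hazard_window"])
        if d.get("exclusion_list") is not None:
            d["exclusion_list"] = tuple(d["exclusion_list"])
        try:
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssessmentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)
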