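"""Quintile classification and extreme-value exclusion.

Scores are cut at their empirical 20/40/60/80th percentiles into classes
1 (lowest) through 5 (highest). Districts on an exclusion list — by
default the provincial capitals, whose outlying adaptive capacity
dominates the maps — are flagged ``"excluded"``; quintile breaks are then
recomputed over the remaining districts only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import HVIError, RosterError

__all__ = ["ClassifiedScores", "classify_quintiles", "exclude_extremes",
           "EXCLUDED"]

EXCLUDED = "excluded"


@dataclass
class ClassifiedScores:
    """Per-district scores, class labels (1..5 int or "excluded") and the
    four interior quantile breaks used."""

    scores: pd.Series
    classes: pd.Series
    breaks: np.ndarray

    def frame(self, name: str = "score") -> pd.DataFrame:
        return pd.DataFrame({name: self.scores,
                             f"{name}_class": self.classes})


def classify_quintiles(scores: pd.Series,
                       quantile_rule: str = "linear") -> ClassifiedScores:
    """Classify scores into quintiles 1..5.

    Interior breaks are the 20/40/60/80th percentiles under
    ``quantile_rule`` (any numpy quantile method name). Intervals are
    half-open with the lowest closed: class k covers [b_{k-1}, b_k), class
    5 is closed above, and scores equal to the observed minimum are always
    class 1 (so an all-tied vector is entirely class 1). Ties share the
    class of their value.
    """
    s = pd.Series(scores).astype(float)
    if s.isna().any():
        raise HVIError("cannot classify missing scores")
    if len(s) < 5:
        raise HVIError(
            f"quintile classification needs >= 5 districts, got {len(s)}")
    breaks = np.quantile(s.to_numpy(), [0.2, 0.4, 0.6, 0.8],
                         method=quantile_rule)
    cls = 1 + np.searchsorted(breaks, s.to_numpy(), side="right")
    cls[s.to_numpy() == s.min()] = 1
    classes = pd.Series(cls.astype(object), index=s.index, name="class")
    return ClassifiedScores(scores=s, classes=classes, breaks=breaks)


def exclude_extremes(scores: pd.Series,
                     exclusion_list: Iterable[str],
                     quantile_rule: str = "linear") -> ClassifiedScores:
    """Classify with listed districts excluded.

    Excluded districts keep their numeric score but get the class marker
    ``"excluded"``; quintile breaks are recomputed on the remainder only.
    """
    s = pd.Series(scores).astype(float)
    excl = set(exclusion_list)
    unknown = excl - set(s.index)
    if unknown:
        raise RosterError(
            f"exclusion list contains unknown districts: {sorted(unknown)}")
    included = s.drop(index=excl)
    inner = classify_quintiles(included, quantile_rule=quantile_rule)
    classes = inner.classes.reindex(s.index)
    classes.loc[list(excl)] = EXCLUDED
    return ClassifiedScores(scores=s, classes=classes, breaks=inner.breaks)
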