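"""Choropleth rendering for classified district scores.

Draws one filled polygon per district from a GeoJSON FeatureCollection,
colored by quintile class on a 5-step sequential palette (yellow to dark
red; reversed for adaptive capacity, where yellow conventionally marks
the *highest* capacity). Excluded districts render grey.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Polygon as MplPolygon, Patch

import pandas as pd

from .classify import ClassifiedScores, EXCLUDED
from .errors import HVIError

__all__ = ["render_choropleth"]

_EXCLUDED_COLOR = "#9e9e9e"


def _class_colors(reverse: bool = False) -> dict[int, tuple]:
    cmap = plt.get_cmap("YlOrRd")
    samples = [cmap(x) for x in (0.1, 0.3, 0.5, 0.7, 0.9)]
    if reverse:
        samples = samples[::-1]
    return {k + 1: samples[k] for k in range(5)}


def _polygon_rings(geometry: dict):
    if geometry["type"] == "Polygon":
        yield geometry["coordinates"][0]
    elif geometry["type"] == "MultiPolygon":
        for poly in geometry["coordinates"]:
            yield poly[0]
    else:
        raise HVIError(
            f"unsupported geometry type {geometry['type']!r}")


def render_choropleth(classified: ClassifiedScores | pd.Series,
                      geometry: dict, path: str | Path,
                      title: str = "", reverse_palette: bool = False,
                      ) -> Path:
    """Render classes onto GeoJSON district polygons and save a PNG.

    ``classified`` is a ClassifiedScores or a plain class Series (values
    1..5 or "excluded") indexed by district_id. Features missing from the
    classification are skipped with a warning; if nothing is renderable,
    raises.
    """
    classes = (classified.classes if isinstance(classified,
                                                ClassifiedScores)
               else pd.Series(classified))
    colors = _class_colors(reverse=reverse_palette)
    fig, ax = plt.subplots(figsize=(7, 8))
    drawn = 0
    for feature in geometry.get("features", []):
        did = feature.get("properties", {}).get("district_id")
        if did not in classes.index:
            warnings.warn(f"district {did!r} missing from classification; "
                          "omitted", stacklevel=2)
            continue
        cls = classes.loc[did]
        color = (_EXCLUDED_COLOR if cls == EXCLUDED
                 else colors[int(cls)])
        for ring in _polygon_rings(feature["geometry"]):
            xs = [pt[0] for pt in ring]
            ys = [pt[1] for pt in ring]
            ax.add_patch(MplPolygon(list(zip(xs, ys)), closed=True,
                                    facecolor=color, edgecolor="black",
                                    linewidth=0.4))
            drawn += 1
    if drawn == 0:
        plt.close(fig)
        raise HVIError("no districts could be rendered")
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    legend = [Patch(facecolor=colors[k], edgecolor="black",
                    label=f"class {k}") for k in range(1, 6)]
    if (classes == EXCLUDED).any():
        legend.append(Patch(facecolor=_EXCLUDED_COLOR, edgecolor="black",
                            label="excluded"))
    ax.legend(handles=legend, loc="lower right", fontsize=8)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
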