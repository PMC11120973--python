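"""Render quintile choropleth maps from a toy district grid.

Real assessments join results to administrative boundary polygons; here a
rectangular-grid GeoJSON stands in so the map machinery can be exercised
anywhere. Classes are colored yellow (lowest) to dark red (highest);
excluded districts render grey; the adaptive-capacity map reverses the
palette so yellow marks the highest capacity.
"""

from pathlib import Path

import hvindex as hv
from hvindex import io as hio
from hvindex.plotting import render_choropleth

out = Path("scratch/maps")
out.mkdir(parents=True, exist_ok=True)

result = hv.run_pipeline(hv.AssessmentConfig(seed=7))
res = result.results

geo = hio.write_geojson_grid(list(res.index), out / "districts.geojson",
                             ncols=13)
render_choropleth(res["hvi_class"], geo, out / "hvi.png",
                  title="HVI quintiles")
render_choropleth(res["hvi_class_excl"], geo, out / "hvi_excl.png",
                  title="HVI quintiles, capitals excluded")
render_choropleth(res["ac_class"], geo, out / "ac.png",
                  title="Adaptive capacity", reverse_palette=True)

for name in ("hvi.png", "hvi_excl.png", "ac.png"):
    print(f"wrote {out / name}")
print("grey cells on hvi_excl.png are the excluded capital districts")
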