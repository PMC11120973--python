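"""Generate a synthetic district panel and look at its structure.

The generator emulates a national assessment's data landscape: 161
districts nested in 11 provinces, one capital per province, a
32-indicator table with sporadic missing cells, monthly climate series
and a 40-year extreme-event record.
"""

import hvindex as hv

panel = hv.generate(hv.GeneratorSpec(seed=7))
rdf = panel.roster_frame

print(f"districts: {len(rdf)}, provinces: {rdf['province_id'].nunique()}, "
      f"capitals: {int(rdf['is_capital'].sum())}")
print(f"indicator table: {panel.table.shape[0]} districts x "
      f"{panel.table.shape[1]} columns, "
      f"{int(panel.table.isna().sum().sum())} missing cells")
print(f"monthly climate rows: {len(panel.monthly_climate)} "
      f"(3 variables x 47 years x 12 months per district)")
print(f"extreme events on record: {len(panel.events)}")
print()
print("first districts:")
print(rdf.head(3)[["name", "province_id", "is_capital", "coastal"]])

# The held-out truth: the latent vulnerability score each district's
# indicators were generated from. The pipeline never sees it; tests use
# it to check that the computed index recovers the planted ranking.
print()
print("latent vulnerability (truth), first 3 districts:")
print(panel.latent.head(3).round(3).to_string())
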