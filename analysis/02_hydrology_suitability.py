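"""Classify rewetting potential and map per-land-use feasible areas.

The 50-cm rule above the outflow-ditch bottom marks the cells
constrained to wet uses (likely open water); cells above the maximum
water level tolerated by the border embankments are constrained to dry
uses; everything between is flexible. Peat thickness and subsoil then
restrict afforestation and agriculture. Writes
results/hydro_classes.csv and results/suitable_areas.csv.
"""

from pathlib import Path

import pandas as pd

from cutaway import classify_hydro, generate_site, kampinneva_like_config, site_suitability

ROOT = Path(__file__).resolve().parents[1]
site = generate_site(kampinneva_like_config(rng_seed=0))

hydro = classify_hydro(site)
classes = pd.DataFrame(
    [{"hydro_class": k, "hectares": v * site.cell_area}
     for k, v in hydro.counts().items()]
)
(ROOT / "results").mkdir(exist_ok=True)
classes.to_csv(ROOT / "results" / "hydro_classes.csv", index=False)

maps = site_suitability(site, hydro)
suitable = pd.DataFrame(
    [{"land_use": u.value, "feasible_ha": a}
     for u, a in maps.feasible_area_ha(site.cell_area).items()]
)
suitable.to_csv(ROOT / "results" / "suitable_areas.csv", index=False)

print(classes.to_string(index=False))
print()
print(suitable.to_string(index=False))
print("\nMost of the site is flexible (rewettable or drainable by ditch "
      "and dam design); only the lowest depressions are constrained to wet uses.")
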