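"""Generate a synthetic village and write it as CSV + GeoJSON.

The generator emulates the three settlement-dispersion regimes of rural
Sahelian villages (uniform, random, clumped) with truncated-Poisson family
sizes and an 18% under-5 share allocated by largest remainder.
"""

from smcplan import VillageSpec, generate_village, write_households

spec = VillageSpec(
    name="demo",
    n_households=126,
    dispersion="random",
    extent_km=2.0,
    mean_family_size=6.0,
    seed=11,
)
village = generate_village(spec)
write_households(village, "demo_village.csv")
write_households(village, "demo_village.geojson")

print(f"village   : {village.name} ({spec.dispersion} dispersion)")
print(f"households: {village.n_households}")
print(f"people    : {village.total_population}")
print(f"under-5   : {village.total_children}")
# The under-5 total is the rounded 18% of the population: these are the
# SMC-eligible children every downstream coverage figure is measured against.
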