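"""Subdivide a hard-to-reach (clumped) village into minimum-size clusters.

Constrained K-means guarantees every cluster at least tau_h households, so
each CHW team gets a workable, contiguous catchment even when plain
K-means would starve one.
"""

from smcplan import VillageSpec, constrained_kmeans, generate_village

village = generate_village(
    VillageSpec(
        name="soaw-like",
        n_households=90,
        dispersion="clumped",
        n_clumps=3,
        extent_km=3.0,
        seed=2,
    )
)
plan = constrained_kmeans(village, k=3, tau=[24, 24, 24], seed=0)

print(f"households    : {village.n_households}")
print(f"cluster sizes : {plan.sizes().tolist()}  (each >= 24 as demanded)")
print(f"objective     : {plan.objective:.3f} km^2 (sum of half squared distances)")
print(f"iterations    : {plan.n_iterations}")
for h in range(plan.k):
    kids = sum(village.households[i].n_under5 for i in plan.indices(h))
    print(f"  cluster {chr(ord('A') + h)}: {plan.sizes()[h]} households, {kids} under-5 children")
# Each cluster is routed and staffed separately downstream, exactly as a
# village split by a river would be campaign-planned in practice.
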