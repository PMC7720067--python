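# Methods

`smcplan` models the microplanning of door-to-door Seasonal Malaria
Chemoprevention (SMC) campaigns: given where households are and how many
under-5 children live in each, it computes how a pair of community health
workers (CHWs) should walk, how long the campaign takes, what fraction of
eligible children it reaches, and how many CHWs full coverage would need.

## Model overview

A campaign on a village is a time-budget problem. One CHW pair works
`campaign_days` days (default 4) of `workday_hours` hours (default 8).
Walking costs `walk_min_per_km` minutes per km (default 20, a wet-season
pace). Treating a household with *c* under-5 children costs, depending on
the treatment model:

| model | duration (min) | meaning |
|---|---|---|
| `current_fixed` | 12.5 × c | observed average under unplanned deployment |
| `optimal_fixed` | 8.5 × c | optimised duration (25 min for a 3-child household) |
| `optimal_draws` | U(10,15), U(15,20), U(20,25) for c = 1, 2, 3 | stochastic per-household variant; c > 3 adds 8.5 min per extra child to a U(20,25) draw |

Key outputs:

- **coverage** = 100 × (treated children) / (eligible children);
- **unmet needs** = (t / T) × 2 CHWs, where t is the treatment-plus-travel
  time in workdays a single pair would need for the whole itinerary and T
  is the campaign duration. The factor 2 converts pairs to individual
  CHWs; fractional results are reported as such (workforce can be shared
  across villages), with an optional integer ceiling for operational use.

### Simulation semantics

`simulate_campaign` walks the itinerary in order against the budget
`chw_pairs × campaign_days` (a pair is the atomic serving unit; fractional
`chw_pairs` scale the budget linearly). A household is either fully served
or skipped: SMC dosing is per child and cannot be split. The walk stops at
the first household whose leg-plus-treatment no longer fits; consequently
the consumed time never exceeds the budget. Day boundaries are ignored —
time is one continuous budget, which matches how the per-component
workday arithmetic composes (e.g. 3.35 + 0.63 ≈ 4 days). Households with
no under-5 children cost walking time but no treatment time. With the
stochastic treatment model, the config seed drives a dedicated generator,
so a run is reproducible and the budget-capped walk and the full-itinerary
time ledger see identical draws.

## Itinerary optimisation (open-path TSP)

Teams visit every household exactly once without returning to the start,
so the objective is the *path* TSP with both endpoints free: minimise the
sum of consecutive pairwise distances over all orderings.

- **Exact solver** (`held_karp_path`): dynamic programming over vertex
  subsets. The implementation augments the instance with a virtual start
  at zero distance from every household; states are (subset, last vertex)
  and the optimum is the cheapest full-subset state — equivalent to
  minimising over all endpoint pairs, with O(2^N·N) states instead of the
  O(2^N·N²) of tabulating both endpoints. The order is recovered by
  backtracking through the table. Memory bounds the method: the default
  `exact_limit` is 15 households, above which the solver refuses and
  directs the caller to the heuristic.
- **Heuristic** (`heuristic_path`): nearest-neighbour construction from
  several seeded starting households, each improved to a 2-opt local
  optimum (segment reversal, first improvement). The result is flagged
  `exact=False`; it can never beat the exact optimum, and on random
  planar instances of 5–10 points it lands within a few percent of it on
  average (asserted in the test suite).
- **Tie-breaking**: among equal-cost predecessors the backtracking picks
  the smallest vertex index, and the final path is reported in the
  lexicographically smaller of its two traversal directions. This makes
  results deterministic; it does not guarantee the globally
  lexicographically minimal optimal path when several distinct optima
  exist (a measure-zero event for continuous coordinates).

**Distances.** `euclidean_local` (default) projects lon/lat to a local
equirectangular metric frame centred on the village centroid and applies
the plane formula; `haversine` computes great-circle distances. Degrees
are not a metric, hence the projection; at village scale (< 20 km) the two
agree to well under 1%, which a test asserts. No road network or barrier
geometry enters the distance model — barrier-split villages are handled by
clustering instead (below), and road-aware routing is out of scope.

## Subdividing hard-to-reach villages (constrained K-means)

Villages partitioned by rivers or distance are split into k clusters, each
planned separately. Plain K-means can produce unusably small clusters, so
the assignment step enforces a minimum size τ_h per cluster: with centres
fixed, assignments minimise Σ T_ih · ½‖x_i − C_h‖² subject to each point
belonging to one cluster and cluster h receiving at least τ_h points. The
constraint matrix is a transportation problem — every basic optimum is
integral — and is solved as a minimum-cost flow (points supply one unit,
clusters demand τ_h, the excess drains to a zero-cost sink) via the
network simplex, with costs scaled to integers at 10⁸ for exact pivoting.
An equivalent direct LP route (`solve_assignment_lp`, HiGHS) is kept and
cross-checked against the flow solution in the tests.

The outer loop alternates assignment with the centroid update (an empty
cluster keeps its centre) and stops when no centre moves more than `tol`
(default 10⁻⁶ km) or after `max_iter` (default 100) iterations. Both
steps can only lower the objective, so it is non-increasing and the loop
converges to a local optimum. Initialisation is seeded k-means++; with all
τ_h = 0 the procedure reduces exactly to Lloyd's algorithm. When τ is not
given, τ_h = floor(0.8·m/k): clusters of roughly equal size with 20%
slack. k is a user decision, as it is in field practice where the analyst
knows where the river runs.

## Household data

**Raster extraction.** Settlement-layer rasters store estimated persons
per pixel. Each pixel with at least `min_persons` (default 1) becomes one
household at the pixel centre with family size `max(1, round(value))` —
the pixel=household equivalence. Co-located dwellings therefore merge into
one larger family; population totals are conserved, household counts can
drop slightly. Supported encodings: single-band north-up GeoTIFF (read via
its ModelPixelScale/ModelTiepoint geo-tags) and the plain-text ESRI ASCII
grid, which is also the write format.

**Under-5 allocation.** The under-5 share of the population defaults to
18%, the typical Sahelian age structure. A per-household fraction is not
an integer, so integer counts are produced by largest-remainder rounding:
quotas 0.18 × family_size are floored and the leftover children (up to the
rounded village total) go to the largest fractional remainders, capped by
family size, ties broken by household order. The village total equals
round(0.18 × population) within ±1 whenever any household has spare
capacity.

**Synthetic villages.** The generator emulates three dispersion regimes:
`uniform` (jittered grid: cells filled row-major deterministically,
jitter up to a fifth of the cell), `random` (homogeneous placement over
the square footprint), and `clumped` (households around n_clumps ≥ 2
hamlet centres drawn in the inner 80% of the footprint with minimum mutual
separation 0.35·extent/√n_clumps, isotropic Gaussian spread 0.04·extent).
The regimes are distinguishable by the relative variance of
nearest-neighbour distances (variance over squared mean), the scale-free
ordering regular < Poisson < clustered; the test suite asserts this on
20-seed averages. Family sizes are zero-truncated Poisson with mean 6 —
plausible rural household sizes; no published family-size law was
available to fit. Coordinates are generated in a local km frame and
anchored to WGS84 at a configurable origin (default near Nanoro, Burkina
Faso), so both the metric and the geographic distance paths are exercised.

What the generator does **not** emulate: real settlement micro-structure
(compounds, paths, building footprints), raster estimation error,
non-stationary density gradients, or absent/refusing families. Passing
tests on synthetic villages validate the algorithms and accounting, not
predictions for any real village.

## Scenario definitions and comparisons

- `current`: a GPS-tracked visit order is replayed when available;
  otherwise a seeded random order emulates un-mapped CHW walking (an
  emulation device, not a claim about real CHW behaviour). Treatment at
  12.5 min/child, one CHW pair.
- `microplan_a`: optimised itinerary and treatment time, one pair.
- `microplan_b`: as A, with `chw_pairs` raised to unmet-needs / 2
  (fractional by default; `ceil_pairs` rounds up).

Proportions of visited households and of treated children between
scenarios are contrasted with the 2×2 chi-square test **with Yates
continuity correction** — the convention under which the reference
contrasts (χ² = 19.15 on 87/242 vs 136/242 visited households and
χ² = 27.76 on 121/324 vs 189/324 treated children) reproduce to the
printed precision; the uncorrected statistic (19.97, 28.60) is available
via `correction=False`. Coverage changes are reported both as percentage
points and as relative percent, since the two readings are easy to
conflate. Uncertainty summaries for per-day child counts and walking
distances use t-distribution confidence intervals
(mean ± t_{(1+level)/2, n−1}·sd/√n).

## Numerical and reporting conventions

- Times are kept at full precision internally; reports round workdays to
  2 decimals, coverage to 1 decimal, CHW needs to 2 decimals.
- Budget comparisons use a 10⁻⁹-minute slack so float accumulation never
  flips a household that exactly fits.
- All randomness (placement, family sizes, treatment draws, heuristic
  starts, k-means++ picks) flows from explicit integer seeds; a pipeline
  run records its seed and re-runs byte-identically.
- Degenerate inputs: an empty extraction yields an empty village with a
  warning; an empty village refuses simulation and routing; a single
  household routes trivially at 0 km; identical scenario proportions give
  a corrected χ² of exactly 0.

## Problem sizes

The test suite and the reproduction script run on desk-scale instances:
exact routing is cross-checked against exhaustive enumeration on 100
random instances of 4–8 households and bounded above the optimum on 50
instances of 5–10; the constrained assignment is enumerated exhaustively
at m ≤ 8; simulations use synthetic villages of 40–126 households, the
scale of the study villages. Larger villages route through the 2-opt
heuristic by design.

## Known limitations

- Walking distances are straight lines; real paths wind. The 20 min/km
  pace partly absorbs this, but no road network is modelled.
- Only day 1 of the 3-day SMC course is planned; later doses are assumed
  caregiver-administered. Vomiting, refusal and absence are not modelled.
- The `current` scenario on synthetic data is an emulation of un-mapped
  walking, suitable for method comparison, not for auditing real teams.
- Exact routing is limited to ~15 households by memory; villages above
  that size get heuristic itineraries flagged `exact=False`.
- The pixel=household equivalence merges co-located dwellings and cannot
  recover household structure finer than the raster resolution.
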