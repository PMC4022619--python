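# Methods

## Scope and assumptions

`aguadanet` models the availability and reachability of seasonal waterholes
for water-dependent wildlife under drought. Its core assumptions:

- **Planar geometry.** Coordinates are projected meters; all distances are
  Euclidean between waterhole centroids. At study extents of a few tens of
  kilometers the planar error is negligible, and centroid-to-centroid links
  avoid the strong rainfall dependence of waterhole edges.
- **Uniform matrix.** The landscape between waterholes is treated as
  uniformly traversable forest: no least-cost or resistance-surface
  distances. Movement thresholds, not matrix quality, limit connectivity.
- **Deterministic drying order.** Drought removes waterholes strictly in
  increasing order of surface area, reflecting the field observation that
  the largest waterholes are the last to dry. No precipitation time series
  or stochastic drying is modelled.
- **Potential, not realized, connectivity.** Distance thresholds come from
  maximum reported travel distances, so results are upper bounds on
  functional connectivity.

## Network extraction

The complete graph on n waterholes has n(n−1)/2 links with Euclidean
lengths. Pruning at a movement threshold d keeps exactly the links with
length ≤ d — the tie at equality is kept, reading "longer than the maximum
movement ability … removed" literally. Link density is
L = links / [n(n−1)/2] (0 when n < 2). Components are computed by
transitive closure over links (scipy `connected_components`); *clusters*
are components with ≥ 2 nodes, and isolated nodes are counted separately
but remain members of the network — they still carry PC self-terms and
habitat buffers.

Distances are computed once on the complete graph and reused across all
prunings and scenario subsets; deleting nodes and pruning by distance
commute, which the test suite asserts on random instances.

## Drought scenarios

The scenario ladder is: base A = all waterholes with area strictly
> 700 m²; B–K additionally remove waterholes with area ≤ T for
T = 1,000, 2,500, 5,625, 10,000, 15,625, 22,500, 30,600, 40,000, 50,600,
62,500 m². The base filter is strict and the scenario filters inclusive —
deliberate, asymmetric readings of "larger than 700 m²" and "smaller than
or equal to T". Equality at a scenario boundary therefore removes the
waterhole.

Default movement thresholds are {3, 5, 10, 13, 16} km, spanning the
reported travel ranges of the three study species; named presets resolve to
tapir {3, 5, 10, 13} km, white-lipped peccary {3, 5, 10, 13, 16} km and
jaguar {2.24, 5, 10} km (the jaguar minimum follows the species literature
value of 2.24 km/day). All distances are free parameters.

## Connectivity metrics

The negative-exponential kernel p(ℓ) = exp(−kℓ) is calibrated per distance
threshold by k = −ln(tail)/d with tail = 0.05: a 5% chance of exceeding the
species' maximum movement distance. Pairwise probabilities p\*ᵢⱼ are the
maximum over paths of the product of link probabilities, computed exactly
as single-source shortest paths under weights −ln p (Dijkstra on a sparse
graph; no all-pairs matrix is materialized above a few thousand nodes).
Since exp(−kℓ) is multiplicative over summed lengths, p\*ᵢⱼ equals
exp(−k · graph-distance(i, j)) when all links use one kernel — the test
suite uses this identity as an independent oracle alongside brute-force
path enumeration.

The PC numerator is Σᵢ Σⱼ aᵢaⱼp\*ᵢⱼ over ordered pairs **including**
self-pairs (p\*ᵢᵢ = 1), the Conefor-style convention; the source analyses
do not state the convention, so a switch (`include_self=False`) excludes
them for sensitivity checks. The numerator is reported raw (m⁴), not
normalized by squared landscape area, to keep scenario comparisons on one
scale. A `component` pair mode (p\* = 1 within a component, 0 across) is
available because a verbal definition by component co-membership is also
defensible; the max-product mode is the default.

Node importance uses patch removal: dPCₖ = 100(PC − PC₋ₖ)/PC with full
recomputation of p\* per removed node — O(n) Dijkstra sweeps per node,
acceptable at the few hundred nodes typical here (≈3 s at n = 187 per
distance). Ranks break ties by larger area, then lexical id. Cross-distance
aggregation sums dPC over the distance list and re-ranks; dPC is not
monotone in area alone — a large but remote waterhole can rank below small,
well-placed stepping stones, which a constructed test instance
demonstrates.

## Habitat buffers

Suitable habitat is the union of per-waterhole buffers (default 1 and
2 km) grown from the waterhole *edge*: the stored polygon footprint when
available, otherwise a 128-segment circle of equal area (area error
< 0.1%; segment count configurable). The union is clipped to the study
boundary before percentages are computed, and patches are the disjoint
polygons of the union; touching buffers count as one patch. Union area is
order-invariant, subadditive and monotone under waterhole deletion, and is
cross-checked against Monte-Carlo point sampling and against a graph
oracle for patch counts.

## Synthetic landscapes

The generator emulates the documented structure of the Calakmul waterhole
layer so the full pipeline is testable without unpublished coordinates:

- **Extent** 30 × 25 km (750 km²); **n = 187** waterholes; a western
  reserve strip covering 35% of the width (the documented 30–40% range).
- **Sizes**: truncated Pareto on [700, 172,500] m² with
  α = 0.7272375, calibrated on the closed-form truncated CDF so the
  expected fraction of sizes ≤ 2,500 m² equals 115/187. This is the
  simplest distribution consistent with a power-law size–frequency plot.
  One consequence: the expected count of waterholes ≥ 40,000 m² is ~7, so
  the far tail is thinner than the documented landscape's; a single
  truncated power law cannot match both counts, and the small-waterhole
  mass governs the drought response, so it wins.
- **Locations**: Thomas-style parent–offspring clustering (12 parents,
  σ = 1,500 m by default) — clumped at the few-kilometer scale the maps
  show, with offspring redrawn (not clipped) at the extent edge.
- **Size–location coupling** (`large_east_bias`, default 0.8): each point
  receives a key mixing its easting rank (weight = bias) with uniform
  noise, and sorted sizes are assigned in key order. Bias 1 gives perfect
  rank correlation between size and easting; bias 0 decouples them. The
  default reproduces the documented pattern of large waterholes aggregated
  close together outside (east of) the reserve.
- **Seeding**: one root seed spawns per-stage substreams
  (`numpy.random.SeedSequence`), so identical configs are bit-identical.

What the generator does **not** emulate: real coordinates and the reserve's
true shape (the strip is rectangular), hydrological or temporal drying
dynamics, and exact printed link counts (7,424 / 209 / 94), which depend on
the unpublished layout. Passing tests on synthetic landscapes therefore
validate the pipeline's mechanics and the qualitative drought response —
the >95% link loss by scenario F and the early collapse of the link-count
curve (its steepest per-step drop at or before scenario C) — not any exact
field number. Note that the *proportional* link density L need not fall
early under size-ordered deletion: deleting nodes uniformly leaves the
expected pair-fraction unchanged, and when surviving large waterholes
aggregate spatially, L rises even as links vanish en masse; the collapse
diagnostic is the link count.

## Numerical choices and degenerate inputs

- Tolerances: footprint-vs-area agreement 0.5%, footprint centroid 1 m,
  reserve-within-boundary 0.1% of reserve area; link-length/threshold
  comparisons use a 1e-9 m guard; CSV round-trips hold to 1e-9 relative.
- A point exactly on the reserve boundary is inside (shapely `covers`).
- Empty scenario results are allowed (severe drought): zero-link, zero-PC
  records and zero-area habitat summaries, not errors.
- A single-node network has L = 0, one isolate, PC = a², and that node's
  dPC = 100.
- Disconnected pairs have p\* = 0 exactly; the diagonal is exactly 1.

## Limitations

- No demography or metapopulation dynamics: connectivity is structural.
- No resistance surfaces, roads or barriers; straight-line distances only.
- The drought ladder is area-ordered and deterministic; real drying
  varies with depth, substrate and rainfall history.
- Habitat quality is binary (buffer membership), unweighted by forest
  condition.
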