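# Methods

## Scope and design

The package is organized as an analysis project: every computation lives in
the library (`src/medaccess/`), and the numbered scripts under `analysis/`
are thin drivers that run one stage each and narrate what they find. The
pipeline is a linear composition: synthetic region → road graph → vehicle
times → drone surface → population rasters → flood classes → vulnerability
scores → Gi* hot spots → station/mode reports. Every stage is deterministic
given the master seed, and the run manifest records the full configuration
plus a SHA-256 hash of every artifact, so reproducibility is checkable byte
for byte.

All geometry uses one projected, meter-unit coordinate system. Vector
layers are shapely geometries in pandas DataFrames, serialized as GeoJSON;
rasters are a small numpy-backed grid container serialized as ESRI ASCII
grids. No CRS transformations are performed anywhere.

## The synthetic region

The generator emulates the data bundle a real study of this kind assembles
from public sources (road centerlines with speed limits, census blocks with
age structure, parcels, building footprints, pharmacy and drone-station
points, land cover, elevation, 100-year-flood and no-fly polygons), with
the statistical and topological structure the analysis depends on:

* **Terrain.** A smooth ridge peaking at 17 m runs along the peninsula's
  spine; elevation falls to sea level faster on the west side, so the
  western fringe lies below the 2 m flood threshold. Flood zones are the
  polygonized cells with `0 ≤ elevation < threshold`; using a threshold on
  synthetic terrain replaces external flood maps while preserving the only
  property used downstream (a binary 100-year zone).
* **Roads.** Level 1 (24.6 m/s ≈ 55 mph) spine along the ridge; level 2
  (13.4 m/s) east–west connectors every 3 km; level 3 (8.9 m/s) local links
  between connectors, with a random 25% of links missing for irregularity.
  All layers share a 1000-m node lattice anchored at the spine, so
  crossings are genuine graph nodes and the mainland network is one
  connected component containing every mainland pharmacy. Edges are
  straight 2-point segments.
* **Island.** A small, low-lying island in the western bay has its own
  local road cross with no mainland connection: its residents cannot drive
  to any pharmacy and appear only in the vehicle "unreachable" row —
  mirroring the real-world pattern of islands served by boat or plane.
* **Blocks and demographics.** Census blocks are an exact banded
  rectangular partition of the mainland (exactly `n_blocks`, no gaps or
  overlaps); the island is one additional block. Block population is
  Poisson(85); the 60+ share is Beta(4.3, 15.7), mean 0.215, matching the
  elderly share typical of rural coastal counties. Blocks are rectangles
  rather than a clipped Voronoi mosaic because the exact-partition property
  (needed by the block join and by mass-conservation tests) is then
  structural rather than numerical.
* **Parcels and buildings.** Parcels are a Voronoi partition of each block
  (seeded by uniform points inside it); each parcel holds 1–3 roughly
  square footprints (6–18 m) scattered around a roadside anchor, because
  residences cluster along roads. Parcels farther than 300 m (a maximum
  driveway length) from every road stay vacant. The largest footprint per
  parcel is the primary residence — the patient location used by all
  downstream stages. About 6% of parcels are commercial (uninhabitable).
* **Facilities.** Five pharmacies sit on the central stretch of the spine
  and two in coastal towns at the east ends of connectors, so the
  peninsula's tips face the longest drives. Drone stations sit on the
  spine, ids numbered north to south. A circular no-fly zone (radius
  2.5 km) covers the northeastern coastal town.
* **Determinism.** Each layer draws from its own stream spawned from the
  master seed (`numpy.random.SeedSequence.spawn`), so regenerating or
  reconfiguring one layer never perturbs the others.

What the generator does **not** emulate: visually realistic coastlines or
road curvature, correlated socioeconomic covariates, traffic, tides, or the
actual geography of any real region. Passing tests therefore demonstrate
the correctness and statistical behavior of the method, not empirical
claims about a particular place; headline percentages depend on the
synthetic geography and are expected to differ from any real deployment.

`plant_cluster` is a first-class testing instrument: it raises the 60+
share of blocks intersecting a disc toward a target and optionally slows
the disc's secondary/local roads, creating a known high-VATF cluster whose
recovery by the hot-spot analysis can be measured across seeds.

## Vehicle routing

Edge minutes are `length / speed / 60`. The graph is undirected with no
turn restrictions or traffic — deliberate simplifications, flagged as
limitations. Routing minimizes minutes only; the hierarchy level is kept as
an edge attribute but carries no routing bonus, since no defensible penalty
scheme presented itself.

Pharmacies are inserted as real nodes by splitting their nearest edge at
the projection point. Residences snap to the nearest point on their nearest
edge (within a 500 m access radius; beyond it a building is unreachable
with a reason code) and their time is the minimum over facilities of
snapped-segment minutes plus node-to-facility shortest-path minutes.
Round-trip minutes are exactly twice one-way minutes. Bins are
left-open/right-closed — a 10.0-minute round trip falls in the "≤10" bin —
so the scoring rubric's "≤ 10 mins" row is honored at the boundary.

Barriers (flood polygons) remove every edge whose **interior** a polygon
intersects; touching at a single point does not sever (conservative
severing). A building whose own snapped edge is severed becomes
unreachable: severed access is treated as blocked rather than re-snapping
to a surviving edge, because a flooded driveway road is not passable even
if a distant road survives.

For population overlays, a zone raster assigns each cell the round-trip bin
of its nearest edge, standing in for network service-area polygons; no
access-radius cutoff applies there (a cell is unreachable only when its
nearest edge is network-disconnected from every pharmacy), since zone
polygons in conventional GIS workflows likewise cover the populated area
around the network.

## Drone delivery times

One-way minutes are `(35 + 45 + dist / 22.35) / 60`: fixed takeoff and
drop-off overheads plus straight-line cruise. The minimum possible time is
80/60 ≈ 1.333 min at zero distance, and the 10-minute service radius is
`(600 − 80) × 22.35 = 11 622 m`. Distances are Euclidean — no detour
routing around no-fly zones; buildings and cells inside a no-fly polygon
are excluded from all drone statistics and from station assignment rather
than rerouted, because a defensible detour model would need operational
inputs the delivery-time model does not include. The building reference
point is the footprint centroid. Station ties break to the lowest station
id.

## Dasymetric population mapping

Within each block, population (total and 60+ separately) is spread
uniformly over habitable cells: cells not in a zero-density land-cover
class (open water, wetland by default — the zero-class list is
configurable) and not under the uninhabitable mask (commercial/government
parcels plus a 30 m buffer on level-1 roads). This is the preset-zero +
areal-weighting path of intelligent dasymetric mapping; sampled class
densities are deliberately omitted — with only one ancillary dataset and no
ground truth, fitted densities would add irreproducibility without
information. Mass is conserved per block to 1e-6 relative. Fallbacks, in
order: a block with no habitable cell spreads uniformly over all of its
cells; a block smaller than one cell puts all mass in the cell containing
its representative point. Both are logged. Cell values are fractional
persons; rounding happens only in reports. Default cell size is 30 m
(the convention of national land-cover products), configurable.

## Vulnerability scoring

Equal-interval rubrics: age share (% of block population 60+) maps
[0,20]→1 … (80,100]→5; round-trip minutes map [0,10]→1 … >40→5; flood
interruption maps its four classes to 1–4 directly. The rubric's
integer-labelled bands ("21–40%") are realized as half-open real intervals
(20, 40] since the underlying quantities are continuous; boundary values
take the lower score. Island residences with no road route score time 5
(their drive time is effectively infinite) and carry a `no_route` flag so
reports can exclude them. VAT = age + time; VATF = VAT + flood; by
construction VATF − VAT equals the flood score, and exhaustive enumeration
of the 5×5×4 grid attains VAT ∈ {2..10} and VATF ∈ {3..14} with both
extremes reached.

Flood classes are assigned with precedence inundated > blocked > detoured >
not affected: inundated iff the footprint intersects a flood polygon
(tested on the polygon, not the centroid); blocked iff no route survives
the barriers; detoured iff the barrier route exceeds baseline by more than
ε = 0.01 min (a guard against floating-point route noise; no principled
threshold exists for "meaningfully longer").

## Getis-Ord Gi*

Binary fixed-distance-band weights with self-inclusion: `w_ij = 1` iff
`d(i,j) ≤ d`. For location i,

```
Gi* = ( Σ_j w_ij x_j − X̄ W_i ) / ( S · sqrt[ (n W_i − W_i²) / (n−1) ] )
```

with `W_i = Σ_j w_ij`, `X̄` the global mean and
`S = sqrt( Σ_j x_j²/n − X̄² )` — the **population** standard deviation
(divisor n); station-summary standard deviations use the same divisor for
consistency. Binary weights make `Σ w²  = W`, which the implementation
exploits. The band distance is the mean over points of the distance to the
k-th nearest neighbor (k = 30 by default) — one concrete reading of "the
average distance between 30 neighboring footprints"; k and the band are
both configurable for sensitivity runs. A constant field raises an error
(S = 0); a point whose band covers all n points has an undefined statistic
and is flagged rather than reported. z-scores classify at |z| ≥ 1.645 /
1.960 / 2.576 (90/95/99%), sign giving hot vs cold. No multiple-testing
correction is applied by default, matching classic hot-spot mapping
practice; the per-point z-table allows any correction downstream.

## Problem sizes and numerical choices

The default region (16 km × 60 km, 120 blocks, ~600 residences, ~1000 road
segments, 30 m rasters) was chosen so a full pipeline run completes in
seconds while every statistic operates far from small-sample degeneracy;
the planted-cluster power study uses 20 seeds with the cluster disc
(radius 3 km, age share boosted to 0.85, local roads slowed to 35%) on the
low-lying western fringe. Graph node snapping merges endpoints within 1 m
via union-find; duplicate edges (same node pair and length) are dropped;
edges with non-positive speed are rejected and logged. Time-bin edges use a
1e-12-relative tolerance so exact multiples of the interval land in the
lower bin deterministically.

## Known limitations

One-way streets, turn penalties, traffic, and speeding behavior are not
modeled; drone endurance, wind, payload and scheduling are not modeled;
flood depth and timing are reduced to a binary 100-year zone; the rubric's
equal-interval scores are coarse summaries of vulnerability (health status
and driving behavior are not represented). These match the stated
boundaries of the analysis rather than accidental gaps.
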