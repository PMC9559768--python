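# Methods

## Problem setting

The package quantifies how a flood changes a population's travel time to
its nearest health facility, and which road segments are critical for that
access. Two engines answer the accessibility question from different
representations of space; a targeted centrality statistic answers the
criticality question. Everything runs on one projected coordinate system
in meters; the tools validate CRS labels and refuse to reproject.

## Network engine

The road network is an undirected graph of classed segments. Under a speed
profile the weight of an edge is its traversal time in minutes,
`length_m / (speed_kmh · 1000/60)`. Class speeds are explicit configuration
with these defaults (km/h):

| class | driving | walking |
|---|---|---|
| trunk | 80 | 5 |
| primary | 60 | 5 |
| secondary | 50 | 5 |
| tertiary | 40 | 5 |
| unclassified | 30 | 5 |
| track | 10 | 5 |
| path | — (not traversable) | 5 |

The driving track speed (10 km/h) and the 2.5 km/h off-road walking speed
used by the friction surface follow the Nelson global-accessibility speed
conventions; the remaining driving speeds are conventional class defaults,
declared rather than hidden inside a routing engine. Walking traverses
every class; whether a cautious pedestrian profile should avoid trunk
roads is an open choice we resolve as "traverse everything" for
comparability between profiles.

Travel time to the nearest facility is one multi-source Dijkstra from all
facility nodes. Facilities snap to the nearest network node within
`max_snap_m` (default 2000 m, ties to the smallest node id). Snapping runs
once against the undisrupted network; in the flooded graph a facility or
origin whose snap node was removed is simply inactive. Re-snapping against
the surviving nodes would let a point enter the graph somewhere else and
could *shorten* some travel times, violating the physical requirement that
a flood never improves access — with single snapping, flood monotonicity
is a theorem (the flooded graph is an edge-subgraph).

Isochrone membership is evaluated directly on the population grid: each
cell takes the minimum time among nodes within `reach_radius_m` (default
500 m) of its center, and cells with no node in radius are out of range —
the grid equivalent of "the network engine does not do open-space
routing". We chose grid evaluation over constructing isochrone polygons
because polygonization conventions (buffer width, concavity) are
arbitrary, while grid membership is deterministic and directly testable; a
cell either has a road within reach or it does not.

## Flood disruption

The flood mask is a polygon union. Disruption removes every graph node
whose coordinates lie inside the union, boundary included (conservative
and deterministic). An edge whose interior crosses the mask while both
endpoints stay dry is **kept** — this is the documented false negative of
node-based removal, preserved deliberately as the default because it is
the procedure the rest of the pipeline is calibrated against;
`strict=True` also drops interior-crossing straight segments.

In the raster engine, cells whose *center* falls inside the union become
impassable. Cell-center membership (vs. any-overlap) was chosen for
determinism and speed; at 1 km cells it misclassifies at most a one-cell
fringe, which the ribbon-area test bounds.

Mask preprocessing merges sources by geometric union and simplifies rings
with Visvalingam–Whyatt: repeatedly remove the vertex whose triangle with
its cyclic neighbours has minimal effective area, with the standard
monotone floor (a recomputed area is floored at the last removed area, so
removal order is a proper ranking), ties to the lowest original vertex
index, stopping at `ceil(retain_fraction · n)` distinct vertices, never
below a triangle. The 1 % retention budget is interpreted per ring. The
pipeline default simplifies each source before merging; the order is not
scientifically constrained and simplify-then-merge keeps per-source
tolerances meaningful.

## Raster engine

The friction surface stores minutes-per-meter per cell. Least-cost time is
a multi-source Dijkstra on the 8-connected cell graph; the step cost
between adjacent cells is the mean of their frictions times the
center-to-center distance (`cell_m`, or `cell_m·√2` diagonally) — the
standard symmetric cost-distance convention. 16-connectivity (knight
moves, `√5` factor) is available as configuration; the defaults and all
oracle tests use 8. Facilities map to their containing cell; several in
one cell collapse to one source; a facility on an impassable cell is
skipped with a warning and it is an error if none remains. Unreachable
cells carry an infinite sentinel, kept distinct from any finite time and
mapped to nodata on output.

## Binning and impact

Times discretize into half-open bins `[k·i, (k+1)·i)` with `i = 10` min,
capped at 60 min driving and 360 min walking; `t ≥ cap` is BEYOND_CAP and
unreachable elements stay a separate label. Population is attributed to
bins by summation; when grids differ in resolution the population is
aggregated by block **sum** only (never interpolation), so every table
conserves the raster total to 1e-6 relative — asserted on every call.

The loss field compares per-cell times before/after flooding: an increase
is `after − before`; reachable-before but unreachable-after (or past the
cap, when one applies) is LOST_ACCESS; a negative increase is physically
impossible under node-removal flooding with fixed snapping, so any that
appears through an artifact is clamped to NO_CHANGE and counted in the
diagnostics. Because binned values carry up to one interval of
quantization, any bin-derived increase is within 10 min of the continuous
increase — a precision bound the tests check directly.

## Targeted edge betweenness centrality

Origins are population nuclei: the population raster is aggregated to a
1 km grid by block sum and every nonzero block contributes its center as
an origin. Destinations per origin are the facilities within a 20 km
planar (Euclidean) buffer — "buffer" is a planar construct, not a network
distance — and `N` counts them **before** any reachability check, so an
in-range but cut-off facility still dilutes the origin's weight; pairs
with no path contribute nothing. Origins with `N = 0` are skipped with a
logged warning.

For each (origin, facility) pair one minimum-travel-time path is selected.
Ties between equal-cost paths are broken by the lexicographically smallest
node-id sequence, reconstructed by a greedy walk on distances-to-
destination (each step must strictly reduce the remaining distance, which
guarantees termination; equality is tested at 1e-9 relative). A single
deterministic path per pair was chosen over fractional splitting across
co-optimal paths: the score is then exactly reproducible and exactly
testable against an enumeration oracle. Scores accumulate as exact
rationals (`Fraction(1, N)`) and are exposed as floats; the conservation
identity Σᵢ TEBC(i) = Σₛ (1/Nₛ)·Σ_d |path(s,d)| is assertable without
tolerance.

Normal-vs-flood classification per edge: FLOODED (removed), LOST (intact,
positive score collapsed to zero), BACKUP_INCREASED (score rose by more
than 1e-9 — the edge absorbs rerouted demand), DECREASED, UNCHANGED.
Dispersion is summarized by the maximum score and the Gini coefficient of
positive scores: near-equal scores mean many alternative routes, a wide
spread means the network hinges on few segments. A population-weighted
variant (weighting origins by their population) is deliberately not
implemented: it privileges large nuclei and renders remote, already
underserved populations invisible, and no precise weighting formula is
established.

## Synthetic scenarios

The generator produces complete, internally consistent scenarios so the
whole pipeline is testable offline. What it emulates — and what it does
not:

- **Road network**: uniform random trunk nodes joined by their Euclidean
  minimum spanning tree (class trunk) plus ~n/3 short shortcuts (primary);
  local nodes scatter around existing nodes (exponential radial decay) and
  attach to their nearest neighbour with secondary/tertiary/track edges.
  The result is fully connected by construction with a sparse backbone and
  denser local fringe. Edges are straight segments (length = Euclidean
  distance); real networks have polyline geometry and cycles in the local
  fabric, so local redundancy is underrepresented.
- **Population**: `n_clusters` Gaussian blobs (σ ~ U(300, 900) m,
  truncated at 3σ) with log-normal masses, renormalized so the sum equals
  the configured total exactly; most cells are exactly zero. Cluster
  centers are placed independently of the road network. Real settlements
  hug roads; this independence makes the network engine's out-of-range
  share high, which mirrors — in exaggerated form — the behaviour of
  road-restricted methods where the mapped network is sparse or
  incomplete relative to where people live.
- **Friction**: per 1 km cell, the fastest traversable road class
  rasterized into it (a cell "contains" a segment if its center is within
  half a cell diagonal) sets the speed, else 2.5 km/h off-road walking.
  No land-cover, slope or river barriers beyond the flood itself.
- **Facilities**: jittered ≤ 200 m around distinct random nodes, clamped
  to the extent.
- **Flood**: a meandering south–north polyline buffered to the configured
  width and clipped to the extent; when `flood_crosses_trunk` is set and a
  network is available, one waypoint is pinned to a trunk node so the
  ribbon provably severs the skeleton. This is a geometric stand-in; no
  hydrology is claimed.

Every generator draws from its own RNG stream derived from the scenario
seed by a fixed offset, so layers are independently reproducible and a
change in one generator's draw count cannot shift another's output.
Default sizes (30 × 30 km extent, 100 m population cells, 1 km friction
cells, 12 trunk + 110 local nodes, 8 facilities, 200 k people in 6
clusters) keep a full two-profile pipeline run under two seconds while
preserving the structural features above; the `small` preset (12 × 12 km)
is used for property sweeps and the hand-built `bridge` preset provides a
fully enumerable answer (origin counts, cut-off population, backup-road
set).

Passing tests on these scenarios demonstrate algorithmic correctness and
the qualitative relationships between the engines; they do not validate
absolute country-scale numbers, which depend on real network completeness,
population placement and flood geometry.

## Numerical choices and degenerate inputs

- Travel-time tie tolerance 1e-9 relative (path reconstruction and
  UNCHANGED classification); snapping ties resolve to the smallest node id.
- UNREACHABLE is `+inf` and IMPASSABLE is `NaN` — sentinels, never large
  finite numbers; both map to nodata in rasters.
- Empty flood mask: disruption is the identity, not an error. A flood
  covering every node yields an empty graph, every cell out of range, and
  zero TEBC scores with a warning.
- All-zero population yields an empty origin set; all-zero TEBC fields
  report Gini 0 with a degenerate flag.
- Grid alignment requires exact integer cell-size ratios; anything else is
  a hard error rather than a silent resample.

## Known limitations

- No one-way streets, turn restrictions, congestion or multimodal chains;
  the graph is undirected and static.
- The node-removal flood rule's false negative for interior-crossing edges
  is preserved by default (see above); strict mode changes the procedure,
  not the mask.
- Isochrone-on-grid evaluation ties the network engine's spatial
  resolution to the population grid and the reach radius.
- The synthetic flood ribbon does not model hydrology, and synthetic
  population ignores road proximity; absolute synthetic-scenario numbers
  carry no real-world meaning.
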