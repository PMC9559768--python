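"""Targeted edge betweenness centrality (TEBC).

Classic edge betweenness counts shortest paths between ALL node pairs.
The targeted variant restricts origins to population nuclei (centroids of
1 km aggregation blocks of the population raster) and destinations to the
health facilities within a 20 km planar buffer of each origin, and weights
every origin's paths by 1/N where N is its in-range facility count — so an
origin surrounded by many facilities spreads one unit of demand across
them.  For each (origin, facility) pair one minimum-travel-time path is
selected (ties broken by the lexicographically smallest node-id sequence)
and every edge on it receives 1/N:

    TEBC(i) = sum over (s, d_s) of g(i; s, d_s) / N(s)

with g = 1 iff the selected path uses edge i.  N counts in-range
facilities regardless of reachability; unreachable pairs contribute
nothing.  Comparing the scores of the normal and the flooded network
classifies each segment: a score collapsing to zero marks a critical road
the flood cuts off, an increasing score marks a backup road absorbing
rerouted demand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import numpy as np

from .grids import PopulationGrid
from .network import FacilitySet, RoadNetwork, TravelGraph, snap_points

logger = logging.getLogger(__name__)

# Edge classification of the normal-vs-flood comparison.
FLOODED = "FLOODED"
LOST = "LOST"
DECREASED = "DECREASED"
UNCHANGED = "UNCHANGED"
BACKUP_INCREASED = "BACKUP_INCREASED"

_EPS = 1e-9


@dataclass(frozen=True)
class Origin:
    x: float
    y: float
    population: float
    node_id: int | None = None


@dataclass
class OriginSet:
    origins: list[Origin]
    aggregation_cell_m: float = 1000.0

    def __len__(self) -> int:
        return len(self.origins)

    def __iter__(self):
        return iter(self.origins)


def population_nuclei(
    pop: PopulationGrid, aggregation_cell_m: float = 1000.0
) -> OriginSet:
    """Population nuclei: centers of nonzero blocks after 1 km aggregation."""
    coarse = pop.coarsen_sum(aggregation_cell_m)
    origins = []
    rs, cs = np.nonzero(coarse.values > 0)
    for r, c in zip(rs, cs):
        x, y = coarse.frame.cell_center(int(r), int(c))
        origins.append(Origin(x, y, float(coarse.values[r, c])))
    return OriginSet(origins, aggregation_cell_m)


def select_destinations(
    origin: Origin, facilities: FacilitySet, range_m: float
) -> tuple[list[int], int]:
    """Facility indices within the planar buffer (inclusive ≤ range_m)."""
    if range_m <= 0:
        raise ValueError("range_m must be > 0")
    sel = [
        i
        for i, f in enumerate(facilities)
        if math.hypot(f.x - origin.x, f.y - origin.y) <= range_m
    ]
    return sel, len(sel)


@dataclass
class TEBCField:
    """Per-edge criticality scores plus per-origin bookkeeping.

    ``exact`` holds the rational accumulation of 1/N contributions keyed by
    edge_id; ``scores`` is its float view. ``origin_records`` carries, per
    origin, the snapped node, N, and the edge count of each selected path —
    enough to assert the mass-conservation identity
    sum_i TEBC(i) = sum_s (1/N_s) * sum_d |path(s, d)|.
    """

    exact: dict[int, Fraction]
    range_m: float
    profile_mode: str
    origin_records: list[dict] = field(default_factory=list)

    @property
    def scores(self) -> dict[int, float]:
        return {e: float(v) for e, v in self.exact.items()}

    def score(self, edge_id: int) -> float:
        return float(self.exact.get(edge_id, 0))

    def total_mass(self) -> Fraction:
        return sum(self.exact.values(), Fraction(0))

    def expected_mass(self) -> Fraction:
        """Right-hand side of the conservation identity, from the records."""
        tot = Fraction(0)
        for rec in self.origin_records:
            n = rec["n_destinations"]
            if n:
                tot += Fraction(sum(rec["path_edge_counts"]), n)
        return tot


def _lexicographic_shortest_path(
    g: nx.Graph, dist_to_d: dict[int, float], start: int, dest: int
) -> list[int] | None:
    """Reconstruct the lexicographically smallest min-time node sequence
    from ``start`` to ``dest`` using distances-to-destination."""
    if start not in dist_to_d or not math.isfinite(dist_to_d[start]):
        return None
    path = [start]
    v = start
    while v != dest:
        dv = dist_to_d[v]
        best = None
        for u in g.neighbors(v):
            du = dist_to_d.get(u)
            if du is None or du >= dv:
                continue  # every step must strictly shrink the remainder
            w = g[v][u]["weight"]
            if abs(du + w - dv) <= _EPS * max(1.0, dv):
                if best is None or u < best:
                    best = u
        if best is None:  # numerically degenerate; should not happen
            return None
        path.append(best)
        v = best
    return path


def tebc_scores(
    graph: TravelGraph,
    origins: OriginSet,
    facilities: FacilitySet,
    range_m: float = 20000.0,
    network: RoadNetwork | None = None,
    max_snap_m: float = 2000.0,
) -> TEBCField:
    """Accumulate 1/N over the selected shortest path of every in-range
    (origin, facility) pair.

    Snapping runs against ``network`` when given (so normal and flooded
    runs share one snap), else against the graph's own nodes; snapped
    nodes absent from the graph are treated as unreachable.
    """
    snap_net = network
    if snap_net is None:
        coords = graph.node_coords()
        snap_net = RoadNetwork({n: xy for n, xy in coords.items()}, [])
    o_nodes = snap_points([(o.x, o.y) for o in origins], snap_net, max_snap_m)
    f_nodes = snap_points([(f.x, f.y) for f in facilities], snap_net, max_snap_m)

    # One Dijkstra per distinct facility node that survives in the graph.
    dist_maps: dict[int, dict[int, float]] = {}
    for fn in {n for n in f_nodes if n is not None and graph.g.has_node(n)}:
        dist_maps[fn] = nx.single_source_dijkstra_path_length(
            graph.g, fn, weight="weight"
        )

    exact: dict[int, Fraction] = {}
    records: list[dict] = []
    skipped_origins = 0
    for o, onode in zip(origins, o_nodes):
        in_range, n = select_destinations(o, facilities, range_m)
        rec = {
            "origin": o,
            "node_id": onode,
            "n_destinations": n,
            "path_edge_counts": [],
        }
        records.append(rec)
        if n == 0:
            logger.warning("origin at (%.0f, %.0f) has no facility in range", o.x, o.y)
            continue
        if onode is None or not graph.g.has_node(onode):
            skipped_origins += 1
            continue
        share = Fraction(1, n)
        for fi in in_range:
            fn = f_nodes[fi]
            if fn is None or fn not in dist_maps:
                continue
            path = _lexicographic_shortest_path(graph.g, dist_maps[fn], onode, fn)
            if path is None:
                continue
            rec["path_edge_counts"].append(len(path) - 1)
            for a, b in zip(path[:-1], path[1:]):
                eid = graph.g[a][b]["edge_id"]
                exact[eid] = exact.get(eid, Fraction(0)) + share
    if skipped_origins:
        logger.warning("%d origins unsnapped or flooded away", skipped_origins)
    if graph.g.number_of_edges() == 0:
        logger.warning("empty graph: all TEBC scores are zero")
    return TEBCField(exact, range_m, graph.profile.mode, records)


@dataclass
class EdgeCriticalityDelta:
    """Per-edge normal-vs-flood comparison."""

    rows: dict[int, dict]  # edge_id -> {score_normal, score_flood, delta, class}

    def classes(self) -> dict[int, str]:
        return {e: r["class"] for e, r in self.rows.items()}


def tebc_delta(
    normal: TEBCField,
    flooded: TEBCField,
    normal_edge_ids: set[int],
    flooded_edge_ids: set[int],
) -> EdgeCriticalityDelta:
    """Classify every edge of the normal network against the flooded run.

    FLOODED: removed by the flood. LOST: intact but its score collapsed
    from positive to zero. BACKUP_INCREASED: score rose (absorbs rerouted
    paths). DECREASED / UNCHANGED otherwise.
    """
    extra = flooded_edge_ids - normal_edge_ids
    if extra:
        raise ValueError(f"flooded graph has edges unknown to the normal one: {extra}")
    rows: dict[int, dict] = {}
    for eid in sorted(normal_edge_ids):
        s0 = normal.score(eid)
        s1 = flooded.score(eid)
        delta = s1 - s0
        if eid not in flooded_edge_ids:
            cls = FLOODED
        elif s0 > _EPS and s1 <= _EPS:
            cls = LOST
        elif delta > _EPS:
            cls = BACKUP_INCREASED
        elif delta < -_EPS:
            cls = DECREASED
        else:
            cls = UNCHANGED
        rows[eid] = {
            "score_normal": s0,
            "score_flood": s1,
            "delta": delta,
            "class": cls,
        }
    return EdgeCriticalityDelta(rows)


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a non-negative sample (0 = all equal)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0 or v.sum() == 0:
        return 0.0
    n = v.size
    total = v.sum()
    # rank formulation: G = 2*sum(i*v_i)/(n*sum(v)) - (n+1)/n with 1-based ranks
    return float(2.0 * np.sum(np.arange(1, n + 1) * v) / (n * total) - (n + 1.0) / n)


def tebc_dispersion(fld: TEBCField) -> dict:
    """Summary of the score distribution: a wide spread (high Gini, one
    dominant edge) signals strong network vulnerability; near-equal scores
    signal many alternatives."""
    scores = np.array([float(v) for v in fld.exact.values() if v > 0])
    if scores.size == 0:
        return {"max": 0.0, "gini": 0.0, "n_positive": 0, "degenerate": True}
    return {
        "max": float(scores.max()),
        "gini": gini(scores),
        "n_positive": int(scores.size),
        "degenerate": False,
    }
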