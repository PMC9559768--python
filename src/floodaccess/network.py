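"""Road networks, travel-time-weighted graphs, and flood disruption.

The road network is an undirected planar graph of classed segments. A speed
profile (walking or driving) turns it into a travel graph whose edge weight
is the traversal time in minutes: ``length_m / (speed_kmh * 1000 / 60)``.
Flooding removes every node lying inside the flood-mask union — the same
node-deletion rule the disaster workflow applies to the source network — so
an edge whose interior crosses the mask but whose endpoints stay dry
survives (a known, deliberate false negative of that rule; ``strict=True``
drops those edges too).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely

from .floodmask import FloodMask

logger = logging.getLogger(__name__)

ROAD_CLASSES = (
    "trunk",
    "primary",
    "secondary",
    "tertiary",
    "unclassified",
    "track",
    "path",
)

#: Marker returned by snap_points for points beyond the snap radius.
UNSNAPPED = None


@dataclass(frozen=True)
class Edge:
    edge_id: int
    node_a: int
    node_b: int
    length_m: float
    road_class: str


@dataclass
class RoadNetwork:
    """Undirected classed road graph embedded in projected meters."""

    nodes: dict[int, tuple[float, float]]
    edges: list[Edge]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.edge_id in seen:
                raise ValueError(f"duplicate edge_id {e.edge_id}")
            seen.add(e.edge_id)
            if e.node_a == e.node_b:
                raise ValueError(f"edge {e.edge_id} is a self-loop")
            for n in (e.node_a, e.node_b):
                if n not in self.nodes:
                    raise ValueError(f"edge {e.edge_id} references unknown node {n}")
            d = self.euclidean(e.node_a, e.node_b)
            if e.length_m < d - 1e-6:
                raise ValueError(
                    f"edge {e.edge_id} length {e.length_m} shorter than "
                    f"endpoint distance {d}"
                )
            if e.road_class not in ROAD_CLASSES:
                raise ValueError(
                    f"edge {e.edge_id}: unknown road_class {e.road_class!r}"
                )

    def euclidean(self, a: int, b: int) -> float:
        (xa, ya), (xb, yb) = self.nodes[a], self.nodes[b]
        return math.hypot(xb - xa, yb - ya)

    def node_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(node_ids, coords) with coords of shape (n, 2), ids sorted."""
        ids = np.array(sorted(self.nodes), dtype=int)
        xy = np.array([self.nodes[i] for i in ids], dtype=float).reshape(-1, 2)
        return ids, xy


@dataclass(frozen=True)
class Facility:
    facility_id: int
    x: float
    y: float


@dataclass
class FacilitySet:
    facilities: list[Facility]

    def __len__(self) -> int:
        return len(self.facilities)

    def __iter__(self):
        return iter(self.facilities)

    def coords(self) -> np.ndarray:
        return np.array([(f.x, f.y) for f in self.facilities], dtype=float)


# Default class speeds in km/h.  The driving profile cannot use foot paths;
# walking uses one flat speed on every class.
DRIVING_SPEEDS = {
    "trunk": 80.0,
    "primary": 60.0,
    "secondary": 50.0,
    "tertiary": 40.0,
    "unclassified": 30.0,
    "track": 10.0,
}
WALKING_SPEEDS = {c: 5.0 for c in ROAD_CLASSES}


@dataclass(frozen=True)
class SpeedProfile:
    mode: str  # "walking" | "driving"
    speeds: dict[str, float] = field(hash=False)
    traversable: frozenset[str] = field(hash=False)

    def __post_init__(self) -> None:
        for c in self.traversable:
            v = self.speeds.get(c, 0.0)
            if v <= 0:
                raise ValueError(f"traversable class {c!r} needs a speed > 0")

    @classmethod
    def driving(cls) -> "SpeedProfile":
        return cls("driving", dict(DRIVING_SPEEDS), frozenset(DRIVING_SPEEDS))

    @classmethod
    def walking(cls) -> "SpeedProfile":
        return cls("walking", dict(WALKING_SPEEDS), frozenset(ROAD_CLASSES))

    @classmethod
    def named(cls, name: str) -> "SpeedProfile":
        if name == "driving":
            return cls.driving()
        if name == "walking":
            return cls.walking()
        raise ValueError(f"unknown profile {name!r}")

    def minutes(self, length_m: float, road_class: str) -> float:
        return length_m / (self.speeds[road_class] * 1000.0 / 60.0)


@dataclass
class TravelGraph:
    """Time-weighted undirected graph. Node attrs x, y; edge attrs
    weight (minutes), length_m, road_class, edge_id."""

    g: nx.Graph
    profile: SpeedProfile

    def edge_ids(self) -> set[int]:
        return {d["edge_id"] for _, _, d in self.g.edges(data=True)}

    def node_coords(self) -> dict[int, tuple[float, float]]:
        return {n: (d["x"], d["y"]) for n, d in self.g.nodes(data=True)}


def build_graph(network: RoadNetwork, profile: SpeedProfile) -> TravelGraph:
    """Weight each traversable segment by its traversal time in minutes."""
    g = nx.Graph()
    for nid, (x, y) in network.nodes.items():
        g.add_node(nid, x=x, y=y)
    for e in network.edges:
        if e.road_class not in ROAD_CLASSES:
            raise ValueError(f"edge {e.edge_id}: unknown road_class {e.road_class!r}")
        if e.road_class not in profile.traversable:
            continue
        w = profile.minutes(e.length_m, e.road_class)
        g.add_edge(
            e.node_a,
            e.node_b,
            weight=w,
            length_m=e.length_m,
            road_class=e.road_class,
            edge_id=e.edge_id,
        )
    return TravelGraph(g, profile)


def apply_flood_to_graph(
    graph: TravelGraph,
    flood: FloodMask,
    network: RoadNetwork | None = None,
    strict: bool = False,
) -> TravelGraph:
    """Remove every node inside the flood union (boundary counts as inside).

    With ``strict=True`` also drops edges whose straight segment crosses the
    mask even though both endpoints are dry — closing the node-rule's
    acknowledged false negative. Off by default so the disruption matches
    the node-deletion procedure.
    """
    if flood.is_empty:
        return TravelGraph(graph.g.copy(), graph.profile)
    nodes = list(graph.g.nodes(data=True))
    xs = np.array([d["x"] for _, d in nodes])
    ys = np.array([d["y"] for _, d in nodes])
    inside = flood.contains_points(xs, ys)
    removed = [n for (n, _), hit in zip(nodes, inside) if hit]
    g = graph.g.copy()
    g.remove_nodes_from(removed)
    if strict:
        drop = []
        for a, b, d in g.edges(data=True):
            seg = shapely.LineString(
                [(g.nodes[a]["x"], g.nodes[a]["y"]), (g.nodes[b]["x"], g.nodes[b]["y"])]
            )
            if seg.intersects(flood.geom):
                drop.append((a, b))
        g.remove_edges_from(drop)
        logger.info("strict flooding dropped %d interior-crossing edges", len(drop))
    logger.info("flood removed %d of %d nodes", len(removed), len(nodes))
    return TravelGraph(g, graph.profile)


def snap_points(
    points: list[tuple[float, float]],
    network: RoadNetwork,
    max_snap_m: float,
) -> list[int | None]:
    """Snap each point to its nearest network node within ``max_snap_m``.

    Exact distance ties resolve to the smallest node_id; points farther
    than the radius from every node map to ``UNSNAPPED`` (None).
    """
    if max_snap_m <= 0:
        raise ValueError("max_snap_m must be > 0")
    ids, xy = network.node_array()
    if ids.size == 0:
        return [UNSNAPPED] * len(points)
    out: list[int | None] = []
    for x, y in points:
        d = np.hypot(xy[:, 0] - x, xy[:, 1] - y)
        dmin = d.min()
        if dmin > max_snap_m:
            out.append(UNSNAPPED)
            continue
        tied = ids[d <= dmin + 1e-9]
        out.append(int(tied.min()))  # ids sorted; min id wins ties
    return out


def nearest_facility_times(
    graph: TravelGraph,
    facilities: FacilitySet,
    network: RoadNetwork,
    max_snap_m: float = 2000.0,
) -> dict[int, float]:
    """Minutes from every graph node to its nearest facility.

    Facilities snap once against the full (undisrupted) network; a facility
    whose snap node is missing from ``graph`` (flooded away) is inactive.
    Nodes with no path to any active facility get ``math.inf``.
    """
    snapped = snap_points([(f.x, f.y) for f in facilities], network, max_snap_m)
    active = [n for n in snapped if n is not None and graph.g.has_node(n)]
    skipped = len(facilities) - len(active)
    if skipped:
        logger.warning("%d facilities unsnapped or flooded away", skipped)
    times: dict[int, float] = {n: math.inf for n in graph.g.nodes}
    if active:
        lengths = nx.multi_source_dijkstra_path_length(
            graph.g, set(active), weight="weight"
        )
        times.update(lengths)
    return times
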