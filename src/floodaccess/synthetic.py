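"""Seeded synthetic scenarios: road network, facilities, population,
friction and flood mask with the statistical structure of the study inputs.

The generators emulate, at desk scale, the shape of the real inputs: a
sparse trunk skeleton with denser local roads hanging off it, population
clustered in a few nuclei with most cells empty, facilities sitting on the
network, a minutes-per-meter friction surface derived from the fastest road
class in each 1 km cell (off-road walking elsewhere), and a ribbon-shaped
flood that severs part of the network.  Every generator is a pure function
of (seed, config): fixed per-generator offsets derive independent RNG
streams from the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from shapely.geometry import LineString, box

from .floodmask import FloodMask
from .grids import Extent, FrictionGrid, GridFrame, PopulationGrid
from .network import (
    Edge,
    Facility,
    FacilitySet,
    RoadNetwork,
    SpeedProfile,
)

# Fixed RNG stream offsets, one per generator.
_STREAM_NETWORK = 1
_STREAM_POPULATION = 2
_STREAM_FACILITIES = 3
_STREAM_FLOOD = 4

#: Off-road walking speed on bare ground, km/h.
OFF_ROAD_WALK_KMH = 2.5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass(frozen=True)
class ScenarioConfig:
    n_trunk_nodes: int = 12
    n_local_nodes: int = 110
    n_facilities: int = 8
    n_population_clusters: int = 6
    total_population: float = 200_000.0
    population_cell_m: float = 100.0
    friction_cell_m: float = 1000.0
    flood_width_m: float = 2500.0
    flood_crosses_trunk: bool = True

    def __post_init__(self) -> None:
        for name in (
            "n_trunk_nodes",
            "n_local_nodes",
            "n_facilities",
            "n_population_clusters",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.population_cell_m <= 0 or self.friction_cell_m <= 0:
            raise ValueError("cell sizes must be > 0")
        ratio = self.friction_cell_m / self.population_cell_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("population_cell_m must divide friction_cell_m")
        if self.total_population <= 0:
            raise ValueError("total_population must be > 0")
        if self.flood_width_m <= 0:
            raise ValueError("flood_width_m must be > 0")


@dataclass
class Scenario:
    seed: int
    extent: Extent
    config: ScenarioConfig
    road_network: RoadNetwork
    facilities: FacilitySet
    population: PopulationGrid
    friction: FrictionGrid
    flood: FloodMask


def gen_road_network(seed: int, extent: Extent, config: ScenarioConfig) -> RoadNetwork:
    """Trunk skeleton (Euclidean MST + a few shortcuts) with local roads.

    Trunk nodes are connected by their minimum spanning tree (class trunk)
    plus ~n/3 short extra links (class primary); each local node attaches to
    the nearest already-placed node with a secondary/tertiary/track edge, so
    the network is fully connected by construction.
    """
    extent.validate()
    rng = _rng(seed, _STREAM_NETWORK)
    mx, my = 0.05 * extent.width, 0.05 * extent.height
    n_t = config.n_trunk_nodes
    pts = np.column_stack(
        [
            rng.uniform(extent.xmin + mx, extent.xmax - mx, n_t),
            rng.uniform(extent.ymin + my, extent.ymax - my, n_t),
        ]
    )
    edges: list[Edge] = []
    eid = 0
    if n_t > 1:
        dm = squareform(pdist(pts))
        mst = minimum_spanning_tree(dm).tocoo()
        for a, b in zip(mst.row, mst.col):
            a, b = int(min(a, b)), int(max(a, b))
            edges.append(Edge(eid, a, b, float(dm[a, b]), "trunk"))
            eid += 1
        present = {(e.node_a, e.node_b) for e in edges}
        order = np.argsort(dm, axis=None)
        extra_target = n_t // 3
        for flat in order:
            if extra_target <= 0:
                break
            a, b = int(flat // n_t), int(flat % n_t)
            if a >= b or (a, b) in present:
                continue
            if rng.random() < 0.5:
                present.add((a, b))
                edges.append(Edge(eid, a, b, float(dm[a, b]), "primary"))
                eid += 1
                extra_target -= 1

    coords = [tuple(p) for p in pts]
    local_classes = np.array(["secondary", "tertiary", "track"])
    local_probs = np.array([0.3, 0.4, 0.3])
    for _ in range(config.n_local_nodes):
        # bias locals toward existing nodes so density clusters around axes
        anchor = coords[int(rng.integers(len(coords)))]
        r = rng.exponential(0.08 * min(extent.width, extent.height))
        th = rng.uniform(0, 2 * math.pi)
        x = float(np.clip(anchor[0] + r * math.cos(th), extent.xmin, extent.xmax))
        y = float(np.clip(anchor[1] + r * math.sin(th), extent.ymin, extent.ymax))
        nid = len(coords)
        d = np.hypot(
            np.array([c[0] for c in coords]) - x,
            np.array([c[1] for c in coords]) - y,
        )
        nearest = int(np.argmin(d))
        coords.append((x, y))
        cls = str(rng.choice(local_classes, p=local_probs))
        length = max(float(d[nearest]), 1.0)
        edges.append(Edge(eid, nearest, nid, length, cls))
        eid += 1

    nodes = {i: (float(x), float(y)) for i, (x, y) in enumerate(coords)}
    return RoadNetwork(nodes, edges)


def gen_population_grid(
    seed: int, extent: Extent, config: ScenarioConfig
) -> PopulationGrid:
    """Clustered population: Gaussian blobs with log-normal masses, most
    cells exactly zero, total conserved to machine precision."""
    rng = _rng(seed, _STREAM_POPULATION)
    frame = GridFrame.from_extent(extent, config.population_cell_m)
    values = np.zeros(frame.shape)
    k = config.n_population_clusters
    masses = rng.lognormal(mean=0.0, sigma=0.8, size=k)
    masses *= config.total_population / masses.sum()
    xs, ys = frame.centers()
    for m in masses:
        cx = rng.uniform(extent.xmin + 0.1 * extent.width, extent.xmax - 0.1 * extent.width)
        cy = rng.uniform(extent.ymin + 0.1 * extent.height, extent.ymax - 0.1 * extent.height)
        sigma = rng.uniform(300.0, 900.0)
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        w = np.where(d2 <= (3 * sigma) ** 2, np.exp(-0.5 * d2 / sigma**2), 0.0)
        total_w = w.sum()
        if total_w <= 0:  # center fell in a cell-free corner; put mass there
            cell = frame.point_to_cell(cx, cy)
            values[cell] += m
        else:
            values += m * (w / total_w)
    # renormalize so the configured total is conserved exactly
    values *= config.total_population / values.sum()
    return PopulationGrid(frame, values)


def _rasterize_speeds(
    network: RoadNetwork,
    frame: GridFrame,
    profile: SpeedProfile,
) -> np.ndarray:
    """Per-cell fastest traversable road speed (0 where no road).

    A segment occupies every cell whose center lies within half a cell
    diagonal of it.
    """
    speeds = np.zeros(frame.shape)
    half_diag = frame.cell_m * math.sqrt(2.0) / 2.0
    xs, ys = frame.centers()
    for e in network.edges:
        if e.road_class not in profile.traversable:
            continue
        v = profile.speeds[e.road_class]
        (xa, ya), (xb, yb) = network.nodes[e.node_a], network.nodes[e.node_b]
        xmin, xmax = min(xa, xb) - half_diag, max(xa, xb) + half_diag
        ymin, ymax = min(ya, yb) - half_diag, max(ya, yb) + half_diag
        c0 = max(0, int((xmin - frame.x0) / frame.cell_m))
        c1 = min(frame.n_cols, int((xmax - frame.x0) / frame.cell_m) + 1)
        r0 = max(0, int((frame.y0 - ymax) / frame.cell_m))
        r1 = min(frame.n_rows, int((frame.y0 - ymin) / frame.cell_m) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        px, py = xs[r0:r1, c0:c1], ys[r0:r1, c0:c1]
        dx, dy = xb - xa, yb - ya
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            dist = np.hypot(px - xa, py - ya)
        else:
            t = np.clip(((px - xa) * dx + (py - ya) * dy) / seg2, 0.0, 1.0)
            dist = np.hypot(px - (xa + t * dx), py - (ya + t * dy))
        hit = dist <= half_diag
        block = speeds[r0:r1, c0:c1]
        block[hit] = np.maximum(block[hit], v)
    return speeds


def gen_friction_grid(
    network: RoadNetwork,
    extent: Extent,
    config: ScenarioConfig,
    speed_profile: SpeedProfile,
    off_road_kmh: float = OFF_ROAD_WALK_KMH,
) -> FrictionGrid:
    """Minutes-per-meter friction: 60/(1000·v) with v the fastest road class
    rasterized into the cell, else the off-road walking speed."""
    frame = GridFrame.from_extent(extent, config.friction_cell_m)
    speeds = _rasterize_speeds(network, frame, speed_profile)
    speeds = np.where(speeds > 0, speeds, off_road_kmh)
    cost = 60.0 / (1000.0 * speeds)
    return FrictionGrid(frame, cost)


def gen_facilities(
    seed: int,
    network: RoadNetwork,
    n: int,
    extent: Extent | None = None,
) -> FacilitySet:
    """Facilities jittered (≤ 200 m) around n distinct random nodes,
    clamped to the extent when one is given."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(network.nodes):
        raise ValueError(f"cannot place {n} facilities on {len(network.nodes)} nodes")
    rng = _rng(seed, _STREAM_FACILITIES)
    ids, xy = network.node_array()
    chosen = rng.choice(len(ids), size=n, replace=False)
    facs = []
    for k, i in enumerate(chosen):
        r = 200.0 * math.sqrt(rng.random())
        th = rng.uniform(0, 2 * math.pi)
        x = xy[i, 0] + r * math.cos(th)
        y = xy[i, 1] + r * math.sin(th)
        if extent is not None:
            x = float(np.clip(x, extent.xmin, extent.xmax))
            y = float(np.clip(y, extent.ymin, extent.ymax))
        facs.append(Facility(k, float(x), float(y)))
    return FacilitySet(facs)


def gen_flood_mask(
    seed: int,
    extent: Extent,
    config: ScenarioConfig,
    network: RoadNetwork | None = None,
) -> FloodMask:
    """Ribbon flood: a meandering south–north polyline buffered to
    ``flood_width_m`` and clipped to the extent.

    When ``flood_crosses_trunk`` and a network is supplied, one waypoint is
    pinned to a trunk node so the ribbon provably severs the skeleton.
    """
    rng = _rng(seed, _STREAM_FLOOD)
    n_way = 8
    ys = np.linspace(extent.ymin - config.flood_width_m, extent.ymax + config.flood_width_m, n_way)
    x_mid = rng.uniform(extent.xmin + 0.25 * extent.width, extent.xmax - 0.25 * extent.width)
    xs = x_mid + np.cumsum(rng.normal(0.0, 0.06 * extent.width, n_way))
    xs = np.clip(xs, extent.xmin, extent.xmax)
    waypoints = list(zip(xs, ys))
    if config.flood_crosses_trunk and network is not None:
        trunk_nodes = sorted(
            {e.node_a for e in network.edges if e.road_class == "trunk"}
            | {e.node_b for e in network.edges if e.road_class == "trunk"}
        )
        if trunk_nodes:
            target = network.nodes[trunk_nodes[int(rng.integers(len(trunk_nodes)))]]
            # pin the vertically nearest waypoint onto the trunk node
            j = int(np.argmin(np.abs(ys - target[1])))
            waypoints[j] = (target[0], target[1])
    ribbon = LineString(waypoints).buffer(config.flood_width_m / 2.0)
    ribbon = ribbon.intersection(box(extent.xmin, extent.ymin, extent.xmax, extent.ymax))
    return FloodMask(ribbon)


def generate_scenario(
    seed: int,
    config: ScenarioConfig | None = None,
    extent: Extent | None = None,
    profile: SpeedProfile | None = None,
) -> Scenario:
    """Assemble a full internally consistent scenario from one seed."""
    config = config or ScenarioConfig()
    extent = extent or Extent(0.0, 0.0, 30_000.0, 30_000.0)
    profile = profile or SpeedProfile.driving()
    net = gen_road_network(seed, extent, config)
    pop = gen_population_grid(seed, extent, config)
    friction = gen_friction_grid(net, extent, config, profile)
    facs = gen_facilities(seed, net, config.n_facilities, extent)
    flood = gen_flood_mask(seed, extent, config, net)
    return Scenario(seed, extent, config, net, facs, pop, friction, flood)


# ---------------------------------------------------------------------------
# Presets


def small_config() -> ScenarioConfig:
    return ScenarioConfig(
        n_trunk_nodes=6,
        n_local_nodes=40,
        n_facilities=4,
        n_population_clusters=4,
        total_population=50_000.0,
        flood_width_m=1500.0,
    )


SMALL_EXTENT = Extent(0.0, 0.0, 12_000.0, 12_000.0)


def preset_scenario(name: str, seed: int) -> Scenario:
    """Named scenario presets: ``small``, ``default`` and the hand-designed
    ``bridge`` fixture."""
    if name == "default":
        return generate_scenario(seed)
    if name == "small":
        return generate_scenario(seed, small_config(), SMALL_EXTENT)
    if name == "bridge":
        return bridge_scenario()
    raise ValueError(f"unknown preset {name!r}")


def bridge_scenario() -> Scenario:
    """Deterministic single-bridge fixture with a hand-enumerable answer.

    Two population nuclei (800 persons near node W1, 200 on the dead-end
    southern spur S) reach the single facility at F over the central bridge
    B1–B2; a northern detour survives the flood, the spur does not::

                  N1--------------N2
                 /                  \\
        W1----Wb----B1--[B2]----Eb----F      [flood covers B1, B2]
                     |
                     S   (dead end)

    Flooding the bridge nodes reroutes W1's demand over the detour
    (backup roads) and cuts off the 200 people at S entirely.
    """
    extent = Extent(0.0, 0.0, 10_000.0, 10_000.0)
    nodes = {
        0: (1500.0, 5500.0),  # W1
        1: (3000.0, 5000.0),  # Wb
        2: (4500.0, 5000.0),  # B1
        3: (5500.0, 5000.0),  # B2
        4: (7000.0, 5000.0),  # Eb
        5: (9000.0, 5000.0),  # F node
        6: (3000.0, 8000.0),  # N1
        7: (7000.0, 8000.0),  # N2
        8: (4500.0, 1500.0),  # S
    }

    def dist(a, b):
        return math.hypot(nodes[a][0] - nodes[b][0], nodes[a][1] - nodes[b][1])

    specs = [
        (0, 1, "trunk"),
        (1, 2, "trunk"),
        (2, 3, "trunk"),  # the bridge
        (3, 4, "trunk"),
        (4, 5, "trunk"),
        (1, 6, "secondary"),
        (6, 7, "secondary"),
        (7, 4, "secondary"),
        (2, 8, "tertiary"),
    ]
    edges = [
        Edge(i, a, b, dist(a, b), cls) for i, (a, b, cls) in enumerate(specs)
    ]
    net = RoadNetwork(nodes, edges)

    config = ScenarioConfig(
        n_trunk_nodes=6,
        n_local_nodes=3,
        n_facilities=1,
        n_population_clusters=2,
        total_population=1000.0,
        flood_width_m=1400.0,
    )
    frame = GridFrame.from_extent(extent, config.population_cell_m)
    values = np.zeros(frame.shape)

    def blob(cx: float, cy: float, total: float) -> None:
        # 3x3 patch of cells centred on (cx, cy): all within 150 m of the
        # node, > 500 m from every other node, inside one 1 km block
        cell = frame.point_to_cell(cx, cy)
        r0, c0 = cell
        values[r0 - 1 : r0 + 2, c0 - 1 : c0 + 2] += total / 9.0

    blob(1500.0, 5500.0, 800.0)  # W1 nucleus, block center (1500, 5500)
    blob(4500.0, 1500.0, 200.0)  # S nucleus, block center (4500, 1500)
    pop = PopulationGrid(frame, values)

    facs = FacilitySet([Facility(0, 9000.0, 5000.0)])
    friction = gen_friction_grid(net, extent, config, SpeedProfile.driving())
    flood = FloodMask.from_rings(
        [
            (
                [
                    (4200.0, 4300.0),
                    (5800.0, 4300.0),
                    (5800.0, 5700.0),
                    (4200.0, 5700.0),
                    (4200.0, 4300.0),
                ],
                [],
            )
        ]
    )
    return Scenario(0, extent, config, net, facs, pop, friction, flood)

#: Edge id of the bridge (B1–B2) in the bridge fixture.
BRIDGE_EDGE_ID = 2
#: Hand-enumerated population cut off entirely when the bridge floods.
BRIDGE_CUTOFF_POPULATION = 200.0
#: Detour edge ids (Wb–N1, N1–N2, N2–Eb) absorbing rerouted demand.
BRIDGE_DETOUR_EDGE_IDS = (5, 6, 7)
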