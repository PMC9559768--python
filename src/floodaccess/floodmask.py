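"""Flood-polygon preprocessing.

A flood mask is a union of polygons delimiting the inundated area. The two
upstream flood-extent products are merged into one vector layer, simplified
with the Visvalingam–Whyatt algorithm (effective triangle area), and queried
with boundary-inclusive point-in-union tests by both accessibility engines.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

Ring = list[tuple[float, float]]


def _validate_ring(ring: Ring, index: int = 0) -> None:
    if len(ring) < 4:
        raise ValueError(f"ring {index}: needs >= 4 points (closed), got {len(ring)}")
    if tuple(ring[0]) != tuple(ring[-1]):
        raise ValueError(f"ring {index}: not closed (first point != last point)")
    lr = shapely.LinearRing(ring)
    if not lr.is_simple or not lr.is_valid:
        raise ValueError(f"ring {index}: self-intersecting or invalid")


@dataclass
class FloodMask:
    """Polygon union (with holes) defining impassable flooded area.

    ``geom`` is a shapely (Multi)Polygon; an empty mask is legal and means
    "no flooding anywhere".
    """

    geom: Polygon | MultiPolygon

    @classmethod
    def empty(cls) -> "FloodMask":
        return cls(Polygon())

    @classmethod
    def from_rings(cls, rings: list[tuple[Ring, list[Ring]]]) -> "FloodMask":
        """Build from (exterior, holes) ring pairs, validating each ring."""
        polys = []
        idx = 0
        for exterior, holes in rings:
            _validate_ring(exterior, idx)
            idx += 1
            for h in holes:
                _validate_ring(h, idx)
                idx += 1
            polys.append(Polygon(exterior, holes))
        return cls(unary_union(polys))

    @property
    def is_empty(self) -> bool:
        return self.geom.is_empty

    @property
    def area_m2(self) -> float:
        return self.geom.area

    def polygons(self) -> list[Polygon]:
        if self.geom.is_empty:
            return []
        if isinstance(self.geom, Polygon):
            return [self.geom]
        return list(self.geom.geoms)

    def contains_point(self, x: float, y: float) -> bool:
        """Boundary-inclusive membership in the flood union."""
        return point_in_mask(x, y, self)

    def contains_points(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Vectorized boundary-inclusive membership test."""
        if self.geom.is_empty:
            return np.zeros(np.shape(xs), dtype=bool)
        pts = shapely.points(np.asarray(xs, float), np.asarray(ys, float))
        return shapely.covers(self.geom, pts)


def merge_masks(a: FloodMask, b: FloodMask) -> FloodMask:
    """Geometric union of two flood masks (same coordinate frame)."""
    return FloodMask(unary_union([a.geom, b.geom]))


def point_in_mask(x: float, y: float, mask: FloodMask) -> bool:
    """True iff the point lies in the union, counting the boundary as inside."""
    if mask.geom.is_empty:
        return False
    return bool(shapely.covers(mask.geom, shapely.Point(x, y)))


def _triangle_area(p0, p1, p2) -> float:
    return 0.5 * abs(
        (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
    )


def simplify_visvalingam(ring: Ring, retain_fraction: float) -> Ring:
    """Visvalingam–Whyatt simplification of a closed ring.

    Iteratively removes the vertex whose triangle with its two (cyclic)
    neighbours has the smallest effective area, ties broken by the lowest
    original vertex index.  Effective areas are monotone: a recomputed
    neighbour area is floored at the area of the last removed vertex, the
    standard trick that makes removal order a proper ranking.  Removal stops
    when ``ceil(retain_fraction * n)`` distinct vertices remain, never fewer
    than 3 (a closed triangle).
    """
    if not (0 < retain_fraction <= 1):
        raise ValueError("retain_fraction must be in (0, 1]")
    _validate_ring(ring)
    pts = [tuple(map(float, p)) for p in ring[:-1]]  # distinct vertices
    n = len(pts)
    target = max(math.ceil(retain_fraction * n), 3)
    if target >= n:
        return [tuple(map(float, p)) for p in ring]

    prev = list(range(-1, n - 1))
    nxt = list(range(1, n + 1))
    prev[0], nxt[-1] = n - 1, 0
    alive = [True] * n

    def area(i: int) -> float:
        return _triangle_area(pts[prev[i]], pts[i], pts[nxt[i]])

    heap: list[tuple[float, int, float]] = []  # (eff_area, index, stamp_area)
    current = [area(i) for i in range(n)]
    for i in range(n):
        heapq.heappush(heap, (current[i], i, current[i]))

    remaining = n
    floor_area = 0.0
    while remaining > target:
        eff, i, stamp = heapq.heappop(heap)
        if not alive[i] or stamp != current[i]:
            continue  # stale heap entry
        floor_area = max(floor_area, eff)
        alive[i] = False
        remaining -= 1
        p, q = prev[i], nxt[i]
        nxt[p], prev[q] = q, p
        for j in (p, q):
            current[j] = max(area(j), floor_area)
            heapq.heappush(heap, (current[j], j, current[j]))

    out = [pts[i] for i in range(n) if alive[i]]
    out.append(out[0])
    return out


def simplify_mask(mask: FloodMask, retain_fraction: float) -> FloodMask:
    """Apply Visvalingam simplification per ring across the whole mask."""
    polys = []
    for poly in mask.polygons():
        ext = simplify_visvalingam(list(poly.exterior.coords), retain_fraction)
        holes = [
            simplify_visvalingam(list(r.coords), retain_fraction)
            for r in poly.interiors
        ]
        p = Polygon(ext, holes)
        if not p.is_valid:  # simplification may rarely fold a ring
            p = p.buffer(0)
        polys.append(p)
    if not polys:
        return FloodMask.empty()
    return FloodMask(unary_union(polys))
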