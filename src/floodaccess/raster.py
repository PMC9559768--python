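"""Raster accessibility engine: least-cost travel time over a friction grid.

The friction surface stores a cost in minutes-per-meter for every cell; a
1 km cell carrying a 10 km/h track therefore costs 6 minutes to cross and
an off-road cell at 2.5 km/h walking costs 24 minutes. Accessibility is the
multi-source shortest path from all facility cells on the 8-connected cell
graph, with the step cost between adjacent cells the mean of their frictions
times the center-to-center distance (cell_m, or cell_m·√2 diagonally).
Flooded cells become impassable before routing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .floodmask import FloodMask
from .grids import FrictionGrid, GridFrame, TimeGrid, UNREACHABLE
from .network import FacilitySet

logger = logging.getLogger(__name__)

#: Bin labels for elements past the profile's time cap / with no path.
BEYOND_CAP_LABEL = -2
UNREACHABLE_LABEL = -1


def cell_traversal_time(cell_m: float, speed_kmh: float) -> float:
    """Minutes to cross one cell of side ``cell_m`` at ``speed_kmh``."""
    if cell_m <= 0 or speed_kmh <= 0:
        raise ValueError("cell_m and speed_kmh must be > 0")
    return cell_m / (speed_kmh * 1000.0 / 60.0)


def apply_flood_to_friction(grid: FrictionGrid, flood: FloodMask) -> FrictionGrid:
    """Cells whose CENTER lies in the flood union become impassable (NaN)."""
    if flood.is_empty:
        return FrictionGrid(grid.frame, grid.values.copy())
    xs, ys = grid.frame.centers()
    inside = flood.contains_points(xs.ravel(), ys.ravel()).reshape(grid.frame.shape)
    values = grid.values.copy()
    values[inside] = np.nan
    logger.info("flood made %d cells impassable", int(inside.sum()))
    return FrictionGrid(grid.frame, values)


_OFFSETS = (
    (0, 1, 1.0),
    (1, 0, 1.0),
    (1, 1, math.sqrt(2.0)),
    (1, -1, math.sqrt(2.0)),
)
_OFFSETS_16 = _OFFSETS + (
    (1, 2, math.sqrt(5.0)),
    (2, 1, math.sqrt(5.0)),
    (1, -2, math.sqrt(5.0)),
    (2, -1, math.sqrt(5.0)),
)


def _cell_graph(grid: FrictionGrid, connectivity: int) -> coo_matrix:
    """Sparse symmetric adjacency of passable cells (flat row-major ids)."""
    nr, nc = grid.frame.shape
    n = nr * nc
    cost = grid.values
    flat = np.arange(n).reshape(nr, nc)
    offsets = _OFFSETS if connectivity == 8 else _OFFSETS_16
    rows, cols, data = [], [], []
    for dr, dc, mult in offsets:
        a_sl = (slice(max(0, -dr), nr - max(0, dr)), slice(max(0, -dc), nc - max(0, dc)))
        b_sl = (slice(max(0, dr), nr - max(0, -dr)), slice(max(0, dc), nc - max(0, -dc)))
        ca, cb = cost[a_sl], cost[b_sl]
        ok = np.isfinite(ca) & np.isfinite(cb)
        w = 0.5 * (ca[ok] + cb[ok]) * grid.frame.cell_m * mult
        rows.append(flat[a_sl][ok])
        cols.append(flat[b_sl][ok])
        data.append(w)
    return coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def least_cost_time(
    grid: FrictionGrid,
    facilities: FacilitySet,
    connectivity: int = 8,
) -> TimeGrid:
    """Minutes from every cell to its nearest facility over the friction grid.

    Facilities map to their containing cell (several in one cell collapse to
    one source); facilities outside the frame or on impassable cells are
    skipped with a warning, and it is an error if none remains.
    """
    if connectivity not in (8, 16):
        raise ValueError("connectivity must be 8 or 16")
    nr, nc = grid.frame.shape
    sources: set[int] = set()
    bad: list[int] = []
    for f in facilities:
        cell = grid.frame.point_to_cell(f.x, f.y)
        if cell is None or not np.isfinite(grid.values[cell]):
            bad.append(f.facility_id)
            continue
        sources.add(cell[0] * nc + cell[1])
    if not sources:
        raise ValueError(
            f"no facility lies on a passable cell (facility ids: {bad})"
        )
    if bad:
        logger.warning("facilities on impassable/outside cells skipped: %s", bad)
    adj = _cell_graph(grid, connectivity)
    dist = dijkstra(adj, directed=False, indices=sorted(sources), min_only=True)
    times = dist.reshape(nr, nc).astype(float)
    times[~np.isfinite(grid.values)] = UNREACHABLE
    return TimeGrid(grid.frame, times)


@dataclass
class AccessBins:
    """Travel times discretized into half-open interval bins.

    Label k covers [k·interval, (k+1)·interval); times at or past the cap
    get BEYOND_CAP_LABEL, unreachable elements UNREACHABLE_LABEL.
    """

    labels: np.ndarray  # int array
    interval_min: float
    cap_min: float
    frame: GridFrame | None = None

    @property
    def n_bins(self) -> int:
        return int(round(self.cap_min / self.interval_min))


def bin_times(
    field: TimeGrid | np.ndarray,
    interval_min: float,
    cap_min: float,
    frame: GridFrame | None = None,
) -> AccessBins:
    """Discretize a travel-time field into 10-min-style half-open bins."""
    if interval_min <= 0 or cap_min <= 0:
        raise ValueError("interval_min and cap_min must be > 0")
    k = cap_min / interval_min
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"interval {interval_min} does not divide cap {cap_min}"
        )
    if isinstance(field, TimeGrid):
        values, frame = field.values, field.frame
    else:
        values = np.asarray(field, dtype=float)
    labels = np.full(values.shape, UNREACHABLE_LABEL, dtype=int)
    finite = np.isfinite(values)
    beyond = finite & (values >= cap_min)
    within = finite & ~beyond
    labels[beyond] = BEYOND_CAP_LABEL
    labels[within] = np.floor(values[within] / interval_min).astype(int)
    return AccessBins(labels, float(interval_min), float(cap_min), frame)
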