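"""Pre/post-flood accessibility comparison and population attribution.

Network-engine node times are materialized on the population grid (each
cell takes the best time among nodes within a reach radius of its center —
the grid form of isochrone membership), populations are summed per travel-
time bin, and the per-cell increase between normal and flooded conditions
is tabulated as a loss-of-access table.  Because times are binned at a
10-minute interval, any bin-derived increase can be off by at most one
interval from the continuous value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import GridFrame, PopulationGrid, TimeGrid, UNREACHABLE
from .network import RoadNetwork
from .raster import AccessBins, BEYOND_CAP_LABEL, UNREACHABLE_LABEL

logger = logging.getLogger(__name__)

# Per-cell loss categories.
NO_CHANGE = 0
INCREASED = 1
LOST_ACCESS = 2


def network_access_grid(
    graph_time: dict[int, float],
    network: RoadNetwork,
    pop: PopulationGrid,
    reach_radius_m: float = 500.0,
) -> TimeGrid:
    """Materialize node travel times on the population grid.

    Each cell receives the minimum time over the nodes within
    ``reach_radius_m`` of its center; cells with no node in radius are
    unreachable (off-network, consistent with a road-restricted engine).
    """
    if reach_radius_m <= 0:
        raise ValueError("reach_radius_m must be > 0")
    frame = pop.frame
    xs, ys = frame.centers()
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    tree = cKDTree(centers)
    out = np.full(centers.shape[0], UNREACHABLE)
    for nid, t in graph_time.items():
        if nid not in network.nodes:
            continue
        x, y = network.nodes[nid]
        idx = tree.query_ball_point([x, y], reach_radius_m)
        if idx:
            idx = np.asarray(idx)
            out[idx] = np.minimum(out[idx], t)
    return TimeGrid(frame, out.reshape(frame.shape))


@dataclass
class ImpactTable:
    """Population attributed to travel-time bins for one engine/condition."""

    bin_pop: np.ndarray  # persons per bin 0..K-1
    beyond_cap: float
    unreachable: float
    interval_min: float
    cap_min: float

    @property
    def total(self) -> float:
        return float(self.bin_pop.sum() + self.beyond_cap + self.unreachable)

    @property
    def n_bins(self) -> int:
        return len(self.bin_pop)

    def labels(self) -> list[str]:
        i = self.interval_min
        return [f"{int(k * i)}-{int((k + 1) * i)} min" for k in range(self.n_bins)]

    def to_frame(self) -> pd.DataFrame:
        rows = self.labels() + ["BEYOND_CAP", "UNREACHABLE"]
        pops = list(self.bin_pop) + [self.beyond_cap, self.unreachable]
        return pd.DataFrame({"bin": rows, "population": pops})


def _align_population(pop: PopulationGrid, frame: GridFrame) -> PopulationGrid:
    if pop.frame.same_frame(frame):
        return pop
    coarse = pop.coarsen_sum(frame.cell_m)  # raises on non-integer ratio
    if not coarse.frame.same_frame(frame):
        raise ValueError("population grid does not align with the access grid")
    return coarse


def population_by_bin(access: AccessBins, pop: PopulationGrid) -> ImpactTable:
    """Sum population per access bin (pop resampled by block sum if coarser
    access cells are used; conservation is exact)."""
    if access.frame is None:
        raise ValueError("access bins carry no grid frame")
    p = _align_population(pop, access.frame).values
    labels = access.labels
    k = access.n_bins
    bin_pop = np.array([p[labels == b].sum() for b in range(k)])
    table = ImpactTable(
        bin_pop,
        float(p[labels == BEYOND_CAP_LABEL].sum()),
        float(p[labels == UNREACHABLE_LABEL].sum()),
        access.interval_min,
        access.cap_min,
    )
    assert abs(table.total - p.sum()) <= 1e-6 * max(p.sum(), 1.0)
    return table


@dataclass
class LossField:
    """Per-cell access change between normal and flooded conditions."""

    frame: GridFrame
    increase_min: np.ndarray  # minutes; 0 where NO_CHANGE, NaN where LOST
    category: np.ndarray  # NO_CHANGE | INCREASED | LOST_ACCESS
    clamped_cells: int  # cells whose raw increase was negative


def access_loss(
    before: TimeGrid,
    after: TimeGrid,
    cap_min: float | None = None,
) -> LossField:
    """Per-cell increase in travel time caused by the flood.

    LOST_ACCESS marks cells reachable before but unreachable after (or past
    ``cap_min`` after, when a cap is given); negative increases — possible
    only through snapping/radius artifacts, a flood cannot improve access —
    are clamped to NO_CHANGE and counted.
    """
    if not before.frame.same_frame(after.frame):
        raise ValueError("before/after grids are on different frames")
    b, a = before.values, after.values
    b_ok = np.isfinite(b)
    a_ok = np.isfinite(a)
    if cap_min is not None:
        b_ok &= b < cap_min
        a_ok &= a < cap_min
    category = np.full(b.shape, NO_CHANGE, dtype=int)
    increase = np.zeros(b.shape)
    lost = b_ok & ~a_ok
    category[lost] = LOST_ACCESS
    increase[lost] = np.nan
    both = b_ok & a_ok
    diff = np.zeros(b.shape)
    diff[both] = a[both] - b[both]
    clamped = int(np.sum(both & (diff < -1e-9)))
    if clamped:
        logger.warning("clamped %d cells with negative loss to NO_CHANGE", clamped)
    pos = both & (diff > 0)
    category[pos] = INCREASED
    increase[pos] = diff[pos]
    return LossField(before.frame, increase, category, clamped)


@dataclass
class LossTable:
    """Population partitioned by the size of its access-time increase."""

    rows: pd.DataFrame  # columns: range, population
    total: float

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def loss_table(
    loss: LossField,
    pop: PopulationGrid,
    interval_min: float = 10.0,
) -> LossTable:
    """Tabulate population by increase range; rows partition the total."""
    p = _align_population(pop, loss.frame).values
    rows: list[tuple[str, float]] = []
    rows.append(("NO_CHANGE", float(p[loss.category == NO_CHANGE].sum())))
    inc = loss.increase_min
    increased = loss.category == INCREASED
    if increased.any():
        kmax = int(np.floor(inc[increased].max() / interval_min))
    else:
        kmax = -1
    for k in range(kmax + 1):
        sel = increased & (inc >= k * interval_min) & (inc < (k + 1) * interval_min)
        rows.append(
            (
                f"+{int(k * interval_min)}-{int((k + 1) * interval_min)} min",
                float(p[sel].sum()),
            )
        )
    rows.append(("LOST_ACCESS", float(p[loss.category == LOST_ACCESS].sum())))
    df = pd.DataFrame(rows, columns=["range", "population"])
    total = float(p.sum())
    assert abs(df["population"].sum() - total) <= 1e-6 * max(total, 1.0)
    return LossTable(df, total)


@dataclass
class ComparisonReport:
    """Side-by-side raster vs network population-by-bin comparison."""

    table: pd.DataFrame  # K + 2 rows
    area_raster_km2: float | None = None
    area_network_km2: float | None = None


def compare_methods(
    raster_table: ImpactTable,
    network_table: ImpactTable,
    raster_area_km2: float | None = None,
    network_area_km2: float | None = None,
) -> ComparisonReport:
    """Bin-by-bin comparison of the two engines' population attribution."""
    if (
        raster_table.interval_min != network_table.interval_min
        or raster_table.cap_min != network_table.cap_min
    ):
        raise ValueError("tables use different bin schemes")
    rf = raster_table.to_frame().rename(columns={"population": "raster_pop"})
    nf = network_table.to_frame().rename(columns={"population": "network_pop"})
    df = rf.merge(nf, on="bin")
    df["abs_diff"] = df["network_pop"] - df["raster_pop"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["pct_diff"] = np.where(
            df["raster_pop"] > 0, 100.0 * df["abs_diff"] / df["raster_pop"], np.nan
        )
    return ComparisonReport(df, raster_area_km2, network_area_km2)


def area_within_threshold(access: AccessBins, threshold_min: float) -> float:
    """km² of cells whose travel time is under the threshold."""
    if access.frame is None:
        raise ValueError("access bins carry no grid frame")
    k = threshold_min / access.interval_min
    if abs(k - round(k)) > 1e-9:
        raise ValueError("threshold must be a multiple of the bin interval")
    k = int(round(k))
    n = int(np.sum((access.labels >= 0) & (access.labels < k)))
    return n * access.frame.cell_m**2 / 1e6
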