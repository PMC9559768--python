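"""Square-cell raster frames and the gridded layers built on them.

All grids share one convention: row-major storage with row 0 at the TOP of
the map, cell (r, c) centered at ``(x0 + (c + 0.5) * cell_m,
y0 - (r + 0.5) * cell_m)``.  Coordinates are projected meters throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for cells that cannot be traversed (friction) — stored as NaN.
IMPASSABLE = float("nan")

#: Sentinel for elements with no path to any facility — stored as +inf,
#: deliberately distinct from any finite travel time.
UNREACHABLE = float("inf")


@dataclass(frozen=True)
class Extent:
    """Axis-aligned rectangle in projected meters."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area_m2(self) -> float:
        return self.width * self.height

    def validate(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"degenerate extent: {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax


@dataclass(frozen=True)
class GridFrame:
    """Geometry of a raster: origin at the top-left corner, square cells."""

    x0: float
    y0: float  # top edge (max y)
    cell_m: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_m <= 0:
            raise ValueError(f"cell_m must be > 0, got {self.cell_m}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @classmethod
    def from_extent(cls, extent: Extent, cell_m: float) -> "GridFrame":
        extent.validate()
        n_cols = int(round(extent.width / cell_m))
        n_rows = int(round(extent.height / cell_m))
        if n_cols < 1 or n_rows < 1:
            raise ValueError("cell size larger than extent")
        return cls(extent.xmin, extent.ymax, cell_m, n_rows, n_cols)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> Extent:
        return Extent(
            self.x0,
            self.y0 - self.n_rows * self.cell_m,
            self.x0 + self.n_cols * self.cell_m,
            self.y0,
        )

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        return (
            self.x0 + (c + 0.5) * self.cell_m,
            self.y0 - (r + 0.5) * self.cell_m,
        )

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of shape (n_rows, n_cols) of cell centers."""
        cs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_m
        rs = self.y0 - (np.arange(self.n_rows) + 0.5) * self.cell_m
        xs, ys = np.meshgrid(cs, rs)
        return xs, ys

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell containing a point, or None if outside the frame."""
        c = int(np.floor((x - self.x0) / self.cell_m))
        r = int(np.floor((self.y0 - y) / self.cell_m))
        # points exactly on the right/bottom frame edge belong to the last cell
        if c == self.n_cols and x == self.x0 + self.n_cols * self.cell_m:
            c -= 1
        if r == self.n_rows and y == self.y0 - self.n_rows * self.cell_m:
            r -= 1
        if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
            return (r, c)
        return None

    def same_frame(self, other: "GridFrame", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell_m - other.cell_m) <= tol
        )

    def coarsen_ratio(self, coarse_cell_m: float, tol: float = 1e-9) -> int:
        """Integer factor by which ``coarse_cell_m`` exceeds this frame's cell.

        Raises ValueError when the ratio is not an integer.
        """
        ratio = coarse_cell_m / self.cell_m
        k = int(round(ratio))
        if k < 1 or abs(ratio - k) > tol:
            raise ValueError(
                f"cell ratio {ratio} is not a positive integer multiple"
            )
        return k


@dataclass
class Raster:
    frame: GridFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.frame.shape:
            raise ValueError(
                f"value shape {self.values.shape} != frame shape {self.frame.shape}"
            )


@dataclass
class FrictionGrid(Raster):
    """Minutes-per-meter cost per cell; NaN marks impassable cells."""

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.all(finite > 0):
            raise ValueError("friction costs must be > 0")

    @property
    def passable(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class PopulationGrid(Raster):
    """Person counts per cell (non-negative, possibly fractional)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("population cells must be finite and >= 0")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def coarsen_sum(self, coarse_cell_m: float) -> "PopulationGrid":
        """Aggregate to a coarser grid by block SUM (never interpolation)."""
        k = self.frame.coarsen_ratio(coarse_cell_m)
        if k == 1:
            return PopulationGrid(self.frame, self.values.copy())
        r, c = self.frame.shape
        nr, nc = -(-r // k), -(-c // k)  # ceil division; pad with zeros
        padded = np.zeros((nr * k, nc * k))
        padded[:r, :c] = self.values
        coarse = padded.reshape(nr, k, nc, k).sum(axis=(1, 3))
        frame = GridFrame(self.frame.x0, self.frame.y0, coarse_cell_m, nr, nc)
        return PopulationGrid(frame, coarse)


@dataclass
class TimeGrid(Raster):
    """Travel time in minutes per cell; +inf marks unreachable cells."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values
        if np.any(np.isnan(vals)) or np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("times must be >= 0 or the UNREACHABLE sentinel")

    @property
    def reachable(self) -> np.ndarray:
        return np.isfinite(self.values)
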