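"""Regular raster grids on a projected metric CRS.

Convention used throughout the package: the grid origin is the lower-left
corner, cells are half-open ``[x0 + j*cell, x0 + (j+1)*cell) x
[y0 + i*cell, y0 + (i+1)*cell)`` and a cell is addressed by its center.
Row index ``i`` increases with y, so ``values[0, 0]`` is the south-west cell.
No-data cells are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "Raster"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: lower-left corner, cell size, shape."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell,
            self.y0 + self.ny * self.cell,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x centers (nx,) and y centers (ny,)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        return xs, ys

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing (x, y).

        Points outside the grid get indices outside ``[0, ny) x [0, nx)``;
        callers are expected to mask them.
        """
        j = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell).astype(int)
        i = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell).astype(int)
        return i, j

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        i, j = self.index_of(x, y)
        return (i >= 0) & (i < self.ny) & (j >= 0) & (j < self.nx)


class Raster:
    """A single-band raster: float values on a :class:`GridSpec`, NaN = no-data."""

    def __init__(self, values: np.ndarray, spec: GridSpec):
        values = np.asarray(values, dtype=float)
        if values.shape != spec.shape:
            raise ValueError(f"values shape {values.shape} != grid shape {spec.shape}")
        self.values = values
        self.spec = spec

    @classmethod
    def full(cls, spec: GridSpec, fill: float = np.nan) -> "Raster":
        return cls(np.full(spec.shape, fill, dtype=float), spec)

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def congruent(self, other: "Raster") -> bool:
        return self.spec == other.spec

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.spec)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell values at point locations; NaN outside the grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        i, j = self.spec.index_of(x, y)
        ok = (i >= 0) & (i < self.spec.ny) & (j >= 0) & (j < self.spec.nx)
        out = np.full(x.shape, np.nan)
        out[ok] = self.values[i[ok], j[ok]]
        return out

    def __eq__(self, other: object) -> bool:  # value equality incl. NaN pattern
        if not isinstance(other, Raster):
            return NotImplemented
        return self.spec == other.spec and np.array_equal(
            self.values, other.values, equal_nan=True
        )
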