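"""Understory-density metric from height-normalized LiDAR returns.

Understory density of a grid cell is the percentage of returns whose
normalized height falls in the understory stratum (default 0.5-5 m,
half-open ``[low, high)``) relative to all returns in the cell.  Cells are
12.5 m by default.  Forest pixels touched by disqualifying management
events (clear-cut before LiDAR acquisition, thinning at any recorded date)
carry no data, as do cells with zero returns — an empty cell is absence of
evidence, not an open understory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .config import RunConfig
from .grids import GridSpec, Raster
from .io import LidarPointSet

log = logging.getLogger(__name__)

__all__ = [
    "ManagementEvent",
    "DensityRaster",
    "ScaleProfile",
    "normalize_heights",
    "understory_density_raster",
    "radial_summary",
    "radius_series",
]


@dataclass(frozen=True)
class ManagementEvent:
    """A recorded forestry intervention over an axis-aligned footprint.

    kind: 'clearcut' or 'thinning'; bbox: (xmin, ymin, xmax, ymax) in metres.
    """

    kind: str
    when: date
    bbox: tuple[float, float, float, float]

    def disqualifies(self, acquisition: date) -> bool:
        """Clear-cuts disqualify only if before acquisition; thinning always."""
        if self.kind == "thinning":
            return True
        if self.kind == "clearcut":
            return self.when < acquisition
        raise ValueError(f"unknown management kind {self.kind!r}")


@dataclass
class DensityRaster:
    """Understory density (%) with congruent forest and no-data masks."""

    density: Raster  # % in [0, 100]; NaN where nodata
    forest_mask: np.ndarray  # bool, True = forest
    nodata_mask: np.ndarray  # bool, True = no usable LiDAR value
    low: float = 0.5
    high: float = 5.0
    acquisition: date | None = None

    def __post_init__(self) -> None:
        if self.forest_mask.shape != self.density.spec.shape:
            raise ValueError("forest mask not congruent with density grid")
        if self.nodata_mask.shape != self.density.spec.shape:
            raise ValueError("nodata mask not congruent with density grid")

    @property
    def spec(self) -> GridSpec:
        return self.density.spec


@dataclass
class ScaleProfile:
    """Per-nest understory summaries across the radius schedule."""

    radii: np.ndarray  # strictly increasing, metres
    mean_ud: np.ndarray  # % per radius, NaN where invalid
    forest_cover: np.ndarray  # proportion per radius
    nodata_fraction: np.ndarray  # proportion per radius
    valid: np.ndarray  # bool per radius

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")

    @property
    def complete(self) -> bool:
        return bool(self.valid.all())


def normalize_heights(points: LidarPointSet, dem: Raster) -> LidarPointSet:
    """Subtract bilinearly interpolated ground elevation from point z values.

    Points outside the DEM's cell-center envelope are dropped (count logged).
    """
    spec = dem.spec
    xs, ys = spec.cell_centers()
    if (
        points.x.size
        and (points.x.max() < xs[0] or points.x.min() > xs[-1]
             or points.y.max() < ys[0] or points.y.min() > ys[-1])
    ):
        raise ValueError("point extent entirely outside the DEM")
    interp = RegularGridInterpolator(
        (ys, xs), dem.values, method="linear", bounds_error=False, fill_value=np.nan
    )
    ground = interp(np.column_stack([points.y, points.x]))
    keep = np.isfinite(ground)
    dropped = int((~keep).sum())
    if dropped:
        log.info("normalize_heights: dropped %d points outside the DEM", dropped)
    normalized = points.points[keep].copy()
    normalized[:, 2] = normalized[:, 2] - ground[keep]
    return LidarPointSet(
        normalized,
        crs_note=points.crs_note,
        acquisition_window=points.acquisition_window,
    )


def understory_density_raster(
    points: LidarPointSet,
    spec: GridSpec,
    low: float,
    high: float,
    forest_mask: np.ndarray,
    management_events: list[ManagementEvent] | None = None,
    acquisition: date | None = None,
) -> DensityRaster:
    """Grid the understory-density metric.

    Per cell: ``100 * #{returns with low <= h < high} / #{all returns}``.
    Non-forest cells are masked; management-disqualified and zero-return
    forest cells become no-data.
    """
    if low >= high:
        raise ValueError("low must be < high")
    if len(points) == 0:
        raise ValueError("point cloud is empty")
    forest_mask = np.asarray(forest_mask, dtype=bool)
    if forest_mask.shape != spec.shape:
        raise ValueError("forest mask not congruent with target grid")

    i, j = spec.index_of(points.x, points.y)
    inside = (i >= 0) & (i < spec.ny) & (j >= 0) & (j < spec.nx)
    flat = i[inside] * spec.nx + j[inside]
    n_cells = spec.ny * spec.nx
    total = np.bincount(flat, minlength=n_cells).astype(float)
    in_stratum = (points.h[inside] >= low) & (points.h[inside] < high)
    under = np.bincount(flat[in_stratum], minlength=n_cells).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(total > 0, 100.0 * under / total, np.nan)
    density = density.reshape(spec.shape)

    zero_return = (total.reshape(spec.shape) == 0) & forest_mask
    if zero_return.any():
        log.info("%d forest cells had zero returns -> nodata", int(zero_return.sum()))

    managed_out = np.zeros(spec.shape, dtype=bool)
    for ev in management_events or []:
        if acquisition is None:
            raise ValueError("management events given but no acquisition date")
        if ev.disqualifies(acquisition):
            managed_out |= _cells_intersecting(spec, ev.bbox) & forest_mask

    nodata = zero_return | managed_out
    values = density.copy()
    values[nodata | ~forest_mask] = np.nan
    return DensityRaster(
        density=Raster(values, spec),
        forest_mask=forest_mask,
        nodata_mask=nodata,
        low=low,
        high=high,
        acquisition=acquisition,
    )


def _cells_intersecting(spec: GridSpec, bbox: tuple[float, float, float, float]) -> np.ndarray:
    """Boolean mask of cells whose square intersects the bbox interior."""
    xmin, ymin, xmax, ymax = bbox
    xs = spec.x0 + np.arange(spec.nx) * spec.cell  # cell left edges
    ys = spec.y0 + np.arange(spec.ny) * spec.cell
    col = (xs < xmax) & (xs + spec.cell > xmin)
    row = (ys < ymax) & (ys + spec.cell > ymin)
    return np.outer(row, col)


def radial_summary(
    raster: DensityRaster,
    center: tuple[float, float],
    radius: float,
    nodata_fraction_max: float = 0.05,
) -> tuple[float, float, float, bool]:
    """Summaries over cells whose centers lie within ``radius`` of ``center``.

    Returns (mean_ud, forest_cover, nodata_fraction, valid).  The mean is over
    valid forest cells; the no-data fraction is relative to forest member
    cells; the buffer is valid when that fraction does not exceed the
    tolerance (default 5%).
    """
    spec = raster.spec
    if radius < spec.cell:
        raise ValueError("radius must be at least one cell size")
    cx, cy = center
    xs, ys = spec.cell_centers()
    # bounding window to avoid scanning the whole grid
    j0 = max(0, int(np.floor((cx - radius - spec.x0) / spec.cell)))
    j1 = min(spec.nx, int(np.ceil((cx + radius - spec.x0) / spec.cell)) + 1)
    i0 = max(0, int(np.floor((cy - radius - spec.y0) / spec.cell)))
    i1 = min(spec.ny, int(np.ceil((cy + radius - spec.y0) / spec.cell)) + 1)
    if j0 >= j1 or i0 >= i1:
        return (np.nan, np.nan, np.nan, False)
    dx = xs[j0:j1] - cx
    dy = ys[i0:i1] - cy
    member = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius**2
    n_member = int(member.sum())
    if n_member == 0:
        return (np.nan, np.nan, np.nan, False)

    forest = raster.forest_mask[i0:i1, j0:j1] & member
    nodata = raster.nodata_mask[i0:i1, j0:j1] & forest
    n_forest = int(forest.sum())
    forest_cover = n_forest / n_member
    if n_forest == 0:
        return (np.nan, forest_cover, np.nan, False)
    nodata_fraction = float(nodata.sum()) / n_forest
    valid = nodata_fraction <= nodata_fraction_max
    usable = forest & ~nodata
    vals = raster.density.values[i0:i1, j0:j1][usable]
    vals = vals[np.isfinite(vals)]
    mean_ud = float(vals.mean()) if vals.size else np.nan
    return (mean_ud, forest_cover, nodata_fraction, valid)


def radius_series(
    raster: DensityRaster,
    center: tuple[float, float],
    config: RunConfig,
    radii: np.ndarray | None = None,
) -> ScaleProfile:
    """The full multi-radius profile for one nest (nest radius + schedule)."""
    radii = config.radii() if radii is None else np.asarray(radii, dtype=float)
    out = np.empty((radii.size, 3))
    valid = np.empty(radii.size, dtype=bool)
    for k, r in enumerate(radii):
        mean_ud, cover, nd_frac, ok = radial_summary(
            raster, center, r, config.nodata_fraction_max
        )
        out[k] = (mean_ud, cover, nd_frac)
        valid[k] = ok
    return ScaleProfile(
        radii=radii,
        mean_ud=out[:, 0],
        forest_cover=out[:, 1],
        nodata_fraction=out[:, 2],
        valid=valid,
    )
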