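"""Landscape extrapolation of the breeding-success model and map validation.

The fitted model is pushed out to rasters: a per-pixel distance-to-
settlement raster, the fixed-effects-only predicted probability of breeding
success (random effects at zero, study-area term at a configured reference
level), zeroing of non-forest pixels and pixels whose understory density
falls outside the range observed at real nests, aggregation to a coarse
validation grid, min-max normalization of both maps and their difference,
and the Pearson correlation between the non-normalized coarse maps.

Sign convention of the difference map: occurrence minus prediction, so
negative values mean the model overestimates breeding success there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve
from scipy.spatial import cKDTree
from scipy.special import expit
from scipy.stats import pearsonr

from .grids import GridSpec, Raster

log = logging.getLogger(__name__)

__all__ = [
    "distance_raster",
    "neighborhood_mean",
    "predict_suitability",
    "aggregate_to_coarse",
    "minmax_normalize",
    "compare_maps",
    "MapComparison",
]


def distance_raster(settlements: np.ndarray, spec: GridSpec) -> Raster:
    """Euclidean distance (m) from every cell center to the nearest settlement."""
    pts = np.asarray(settlements, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("settlement point set is empty")
    tree = cKDTree(pts)
    xs, ys = spec.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    dist, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), k=1)
    return Raster(dist.reshape(spec.shape), spec)


def neighborhood_mean(raster: Raster, radius: float) -> Raster:
    """Mean of valid cells whose centers lie within ``radius`` of each cell center.

    Implemented as a disc-kernel convolution ignoring NaN cells; a cell with
    no valid neighbour stays NaN.
    """
    spec = raster.spec
    r_cells = int(np.floor(radius / spec.cell))
    offs = np.arange(-r_cells, r_cells + 1)
    kernel = (offs[:, None] ** 2 + offs[None, :] ** 2) * spec.cell**2 <= radius**2
    kernel = kernel.astype(float)
    vals = raster.values
    valid = np.isfinite(vals).astype(float)
    filled = np.where(np.isfinite(vals), vals, 0.0)
    s = convolve(filled, kernel, mode="constant", cval=0.0)
    c = convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(c > 0, s / c, np.nan)
    return Raster(out, spec)


def predict_suitability(
    coefs: dict[str, float],
    ud_raster: Raster,
    dist_raster: Raster,
    forest_mask: np.ndarray,
    nesting_ranges: dict[str, tuple[float, float]],
    breakpoint: float,
    area: str | np.ndarray = "managed",
    ud_log_floor: float = 0.1,
) -> Raster:
    """Fixed-effects-only predicted probability of breeding success per pixel.

    ``coefs`` holds intercept, area_unmanaged, close, log_ud and
    close_x_log_ud on the logit scale.  ``area`` is either a reference level
    applied everywhere or a boolean array marking unmanaged pixels.
    Probability is set to exactly 0 on non-forest pixels and on pixels whose
    understory density lies outside the proximity-specific nesting range;
    pixels with no density value stay no-data.
    """
    spec = ud_raster.spec
    if dist_raster.spec != spec:
        raise ValueError("density and distance rasters are not congruent")
    forest_mask = np.asarray(forest_mask, dtype=bool)
    if forest_mask.shape != spec.shape:
        raise ValueError("forest mask not congruent")

    ud = ud_raster.values
    dist = dist_raster.values
    close = dist < breakpoint
    if isinstance(area, str):
        unmanaged = np.full(spec.shape, 1.0 if area == "unmanaged" else 0.0)
    else:
        unmanaged = np.asarray(area, dtype=float)

    log_ud = np.log(np.maximum(ud, ud_log_floor))
    eta = (
        coefs["intercept"]
        + coefs["area_unmanaged"] * unmanaged
        + coefs["close"] * close
        + coefs["log_ud"] * log_ud
        + coefs["close_x_log_ud"] * close * log_ud
    )
    p = expit(eta)

    lo_c, hi_c = nesting_ranges["close"]
    lo_f, hi_f = nesting_ranges["far"]
    in_range = np.where(
        close, (ud >= lo_c) & (ud <= hi_c), (ud >= lo_f) & (ud <= hi_f)
    )
    p = np.where(forest_mask & in_range, p, 0.0)
    p = np.where(np.isnan(ud) & forest_mask, np.nan, p)  # no LiDAR value: unknown, not 0
    return Raster(p, spec)


def aggregate_to_coarse(fine: Raster, coarse_cell: float) -> Raster:
    """Block means onto a coarse grid anchored at the fine grid's origin.

    A coarse value is the mean over the fine cells whose centers fall in the
    coarse cell, skipping no-data fine cells; it is no-data only when every
    member cell is.
    """
    spec = fine.spec
    if coarse_cell <= spec.cell:
        raise ValueError("coarse cell must exceed the fine cell size")
    xs, ys = spec.cell_centers()
    jc = np.floor((xs - spec.x0) / coarse_cell).astype(int)
    ic = np.floor((ys - spec.y0) / coarse_cell).astype(int)
    nxc, nyc = jc.max() + 1, ic.max() + 1
    flat = (ic[:, None] * nxc + jc[None, :]).ravel()
    vals = fine.values.ravel()
    ok = np.isfinite(vals)
    sums = np.bincount(flat[ok], weights=vals[ok], minlength=nxc * nyc)
    counts = np.bincount(flat[ok], minlength=nxc * nyc)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / counts, np.nan)
    cspec = GridSpec(x0=spec.x0, y0=spec.y0, cell=coarse_cell, nx=nxc, ny=nyc)
    return Raster(out.reshape(nyc, nxc), cspec)


def minmax_normalize(raster: Raster) -> Raster:
    """z = (x - min) / (max - min) over valid cells; no-data preserved."""
    vals = raster.values
    vmin, vmax = np.nanmin(vals), np.nanmax(vals)
    if not vmax > vmin:
        raise ValueError("min-max normalization undefined for a constant raster")
    return Raster((vals - vmin) / (vmax - vmin), raster.spec)


@dataclass
class MapComparison:
    diff: Raster  # occurrence_norm - prediction_norm
    ppmc: float
    n_cells: int
    region_summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    note: str = ""


def compare_maps(
    pred_coarse: Raster,
    occ_coarse: Raster,
    regions: dict[str, np.ndarray] | None = None,
    quantiles: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> MapComparison:
    """Difference map and Pearson correlation of prediction vs occurrence.

    The difference uses min-max normalized rasters (occurrence minus
    prediction); the correlation uses the non-normalized values over jointly
    valid cells.  Optional ``regions`` (name -> boolean mask on the coarse
    grid) get per-region quantile summaries of the difference.
    """
    if pred_coarse.spec != occ_coarse.spec:
        raise ValueError("coarse rasters are not congruent")
    joint = np.isfinite(pred_coarse.values) & np.isfinite(occ_coarse.values)
    n_joint = int(joint.sum())
    if n_joint < 3:
        raise ValueError("need at least 3 jointly valid coarse cells")

    note = ""
    pv = pred_coarse.values[joint]
    ov = occ_coarse.values[joint]
    if np.ptp(pv) == 0 or np.ptp(ov) == 0:
        ppmc = np.nan
        note = "ppmc undefined: zero variance in at least one raster"
    else:
        ppmc = float(pearsonr(pv, ov)[0])

    def _norm(r: Raster) -> Raster:
        if np.nanmax(r.values) > np.nanmin(r.values):
            return minmax_normalize(r)
        # a constant raster has no min-max scale; map it to 0 so the diff
        # degrades gracefully alongside the undefined ppmc
        return Raster(np.where(np.isfinite(r.values), 0.0, np.nan), r.spec)

    pred_norm = _norm(pred_coarse)
    occ_norm = _norm(occ_coarse)
    diff = Raster(occ_norm.values - pred_norm.values, pred_coarse.spec)

    summaries: dict[str, dict[str, float]] = {}
    for name, mask in (regions or {}).items():
        sel = diff.values[np.asarray(mask, dtype=bool) & joint]
        sel = sel[np.isfinite(sel)]
        if sel.size == 0:
            summaries[name] = {}
            continue
        summaries[name] = {f"q{int(q * 100):02d}": float(np.quantile(sel, q)) for q in quantiles}
        summaries[name]["mean"] = float(sel.mean())
        summaries[name]["n"] = int(sel.size)

    return MapComparison(
        diff=diff, ppmc=ppmc, n_cells=n_joint, region_summaries=summaries, note=note
    )
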