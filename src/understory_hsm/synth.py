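"""Synthetic scenes with the statistical structure the analysis assumes.

Every downstream stage is tested against data from these generators, whose
ground truth is known exactly: a spatially autocorrelated understory field
(% of returns in the 0.5-5 m stratum), a forest mask, Poisson-scattered
settlements, a LiDAR point cloud whose per-cell stratum counts are
binomially thinned from the field, Bernoulli breeding outcomes from a
logistic truth with crossed year/female/male random intercepts, logistic
predator-occurrence observations, and a noisy coarse occurrence raster for
map validation.

The generating coefficients default to the fitted values of the study this
package models (logit scale: intercept 0.24, unmanaged area -0.52, close to
settlement 1.04, log understory 0.40, close x log understory -1.57;
predator occurrence intercept 3.948 and slope -0.003 per metre, i.e. a
1,316 m switch distance; proximity breakpoint 1,450 m), and the understory
field defaults (mean 13%, SD 6%) match that study's site-level summaries.
Year/breeder variance components are not reported there; the default of
0.5 each is a configurable, deliberately moderate choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.special import expit

from .config import RunConfig, rng_for
from .grids import GridSpec, Raster
from .landscape import aggregate_to_coarse, distance_raster, neighborhood_mean, predict_suitability

log = logging.getLogger(__name__)

__all__ = [
    "SceneTruth",
    "generate_landscape",
    "generate_point_cloud",
    "generate_nests",
    "generate_jay_observations",
    "generate_occurrence_raster",
    "true_suitability",
    "DEFAULT_GLMM_TRUTH",
    "DEFAULT_JAY_TRUTH",
]

DEFAULT_GLMM_TRUTH = {
    "beta": {
        "intercept": 0.24,
        "area_unmanaged": -0.52,
        "close": 1.04,
        "log_ud": 0.40,
        "close_x_log_ud": -1.57,
    },
    "sigma2": {"year": 0.5, "breeder_f": 0.5, "breeder_m": 0.5},
}

DEFAULT_JAY_TRUTH = (3.948, -0.003)  # logit intercept, slope per metre


@dataclass
class SceneTruth:
    """A generated landscape plus everything needed to check estimators."""

    understory: Raster  # % in [0, 100]
    forest_mask: np.ndarray
    settlements: np.ndarray  # (k, 2)
    managed_split_x: float  # x < split -> managed, else unmanaged
    glmm_truth: dict
    jay_truth: tuple[float, float]
    true_breakpoint: float
    config: RunConfig = field(default_factory=RunConfig)

    @property
    def spec(self) -> GridSpec:
        return self.understory.spec

    def unmanaged_mask(self) -> np.ndarray:
        xs, _ = self.spec.cell_centers()
        return np.broadcast_to(xs[None, :] >= self.managed_split_x, self.spec.shape).copy()


def generate_landscape(
    extent: tuple[float, float],
    config: RunConfig | None = None,
    seed: int = 0,
    mean_ud: float = 13.0,
    sd_ud: float = 6.0,
    corr_range: float = 100.0,
    settlement_intensity: float = 0.05,  # points per km^2
    forest_fraction: float = 0.85,
    glmm_truth: dict | None = None,
    jay_truth: tuple[float, float] = DEFAULT_JAY_TRUTH,
    true_breakpoint: float = 1450.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> SceneTruth:
    """Generate the scene: understory field, forest mask, settlements, truth.

    The understory field is Gaussian white noise smoothed to the requested
    correlation range, restandardized to (mean_ud, sd_ud) and clipped to
    [0, 100].  Settlements are a homogeneous Poisson process.  The west
    53/83 share of the extent is the managed area, mirroring the relative
    sizes of a managed and an adjoining unmanaged study area.
    """
    width, height = extent
    if width <= 0 or height <= 0:
        raise ValueError("extent must have positive area")
    if width * height < 1e6:
        raise ValueError("extent must be at least 1 km^2")
    config = config or RunConfig()
    cell = config.grid_cell_size
    nx, ny = int(round(width / cell)), int(round(height / cell))
    spec = GridSpec(x0=origin[0], y0=origin[1], cell=cell, nx=nx, ny=ny)

    rng = rng_for(seed, "landscape")
    white = rng.normal(size=spec.shape)
    if corr_range > 0:
        smooth = gaussian_filter(white, sigma=corr_range / cell, mode="reflect")
    else:
        smooth = white
    s = smooth.std()
    if s > 0:
        smooth = (smooth - smooth.mean()) / s
    field_vals = np.clip(mean_ud + sd_ud * smooth, 0.0, 100.0)

    white2 = rng.normal(size=spec.shape)
    smooth2 = gaussian_filter(white2, sigma=max(corr_range, cell) / cell, mode="reflect")
    if forest_fraction >= 1.0:
        forest = np.ones(spec.shape, dtype=bool)
    else:
        forest = smooth2 < np.quantile(smooth2, forest_fraction)

    area_km2 = width * height / 1e6
    n_settle = rng.poisson(settlement_intensity * area_km2)
    settlements = np.column_stack(
        [
            origin[0] + rng.uniform(0, width, n_settle),
            origin[1] + rng.uniform(0, height, n_settle),
        ]
    )

    split_x = origin[0] + width * 53.0 / 83.0
    return SceneTruth(
        understory=Raster(field_vals, spec),
        forest_mask=forest,
        settlements=settlements,
        managed_split_x=split_x,
        glmm_truth=glmm_truth or DEFAULT_GLMM_TRUTH,
        jay_truth=jay_truth,
        true_breakpoint=true_breakpoint,
        config=config,
    )


def generate_point_cloud(
    understory: Raster,
    forest_mask: np.ndarray,
    pulse_density: float,
    seed: int = 0,
    ground_fraction: float = 0.2,
    low: float = 0.5,
    high: float = 5.0,
    canopy_max: float = 20.0,
):
    """Simulate height-normalized LiDAR returns over the scene grid.

    Per cell: total returns ~ Poisson(pulse_density x cell area); returns in
    the understory stratum ~ Binomial(total, field/100) with heights uniform
    in [low, high); the rest split between ground (h in [0, low)) and canopy
    (h in [high, canopy_max)) by ``ground_fraction``.  Height distributions
    within strata are uniform on purpose — only stratum membership feeds the
    density metric.
    """
    from .io import LidarPointSet

    if not 0.1 <= pulse_density <= 10:
        raise ValueError("pulse_density must be in [0.1, 10] points/m^2")
    forest_mask = np.asarray(forest_mask, dtype=bool)
    spec = understory.spec
    if forest_mask.shape != spec.shape:
        raise ValueError("field and forest mask grids do not match")

    rng = rng_for(seed, "point_cloud")
    lam = pulse_density * spec.cell**2
    total = rng.poisson(lam, size=spec.shape)
    p_under = np.clip(understory.values / 100.0, 0.0, 1.0)
    n_under = rng.binomial(total, p_under)
    rest = total - n_under
    n_ground = rng.binomial(rest, ground_fraction)
    n_canopy = rest - n_ground

    iy, ix = np.indices(spec.shape)
    parts = []
    for counts, h_lo, h_hi in (
        (n_under, low, high),
        (n_ground, 0.0, low),
        (n_canopy, high, canopy_max),
    ):
        c = counts.ravel()
        n_tot = int(c.sum())
        if n_tot == 0:
            continue
        cell_i = np.repeat(iy.ravel(), c)
        cell_j = np.repeat(ix.ravel(), c)
        x = spec.x0 + (cell_j + rng.uniform(size=n_tot)) * spec.cell
        y = spec.y0 + (cell_i + rng.uniform(size=n_tot)) * spec.cell
        h = rng.uniform(h_lo, h_hi, size=n_tot)
        parts.append(np.column_stack([x, y, h]))
    pts = np.concatenate(parts) if parts else np.empty((0, 3))
    return LidarPointSet(pts, crs_note="synthetic scene grid")


def _field_mean_in_radius(
    raster: Raster, x: float, y: float, radius: float, mask: np.ndarray | None = None
) -> float:
    """Mean field value over cells whose centers lie within radius of (x, y).

    With ``mask`` given (e.g. the forest mask) only masked-true cells enter,
    matching the definition the extraction stage uses.
    """
    spec = raster.spec
    xs, ys = spec.cell_centers()
    j0 = max(0, int((x - radius - spec.x0) / spec.cell))
    j1 = min(spec.nx, int((x + radius - spec.x0) / spec.cell) + 2)
    i0 = max(0, int((y - radius - spec.y0) / spec.cell))
    i1 = min(spec.ny, int((y + radius - spec.y0) / spec.cell) + 2)
    dx = xs[j0:j1] - x
    dy = ys[i0:i1] - y
    member = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius**2
    if mask is not None:
        member = member & mask[i0:i1, j0:j1]
    vals = raster.values[i0:i1, j0:j1][member]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def generate_nests(
    scene: SceneTruth,
    n_nests: int,
    n_years: int = 16,
    pair_persistence: float = 0.8,
    seed: int = 0,
    first_year: int = 1998,
    territory_jitter: float = 150.0,
    n_renest: int = 0,
    n_treated: int = 0,
    breakpoint: float | None = None,
    ud_col_radius: float | None = None,
) -> pd.DataFrame:
    """Simulate breeding events with crossed year/breeder random effects.

    Territories are fixed forest locations; each breeds once a year at a
    forest cell within ``territory_jitter`` of its center.  Each breeder
    persists to the next season with probability ``pair_persistence``
    (geometric tenure), which induces the crossed repeated-measures
    structure.  Success is Bernoulli on the logit scale:

        eta = b0 + b_area 1[unmanaged] + b_close 1[d < breakpoint]
              + b_logud ln(ud) + b_int 1[close] ln(ud) + u_year + u_F + u_M

    with ud the true mean understory density within the nest radius.
    """
    if n_nests < 1:
        raise ValueError("n_nests must be >= 1")
    cfg = scene.config
    spec = scene.spec
    rng = rng_for(seed, "nests")
    bp = scene.true_breakpoint if breakpoint is None else breakpoint
    radius = cfg.nest_radius if ud_col_radius is None else ud_col_radius

    forest_i, forest_j = np.nonzero(scene.forest_mask)
    if forest_i.size == 0:
        raise ValueError("no forest cells available for nest placement")
    xs, ys = spec.cell_centers()
    fx, fy = xs[forest_j], ys[forest_i]
    forest_tree = cKDTree(np.column_stack([fx, fy]))

    n_pairs = math.ceil(n_nests / n_years)
    centers_idx = rng.choice(fx.size, size=n_pairs, replace=fx.size < n_pairs)
    if np.isfinite(territory_jitter):
        neighbour_lists = forest_tree.query_ball_point(
            np.column_stack([fx[centers_idx], fy[centers_idx]]), territory_jitter
        )
    else:
        # site fidelity off: every breeding attempt at an independent
        # random forest cell (used to isolate spatial-scale questions
        # from territory clustering)
        neighbour_lists = None

    beta = scene.glmm_truth["beta"]
    sigma2 = scene.glmm_truth["sigma2"]
    u_year = rng.normal(0, np.sqrt(sigma2["year"]), size=n_years)

    next_id = {"f": 0, "m": 0}

    def new_breeder(sex: str) -> tuple[str, float]:
        next_id[sex] += 1
        return (
            f"{sex.upper()}{next_id[sex]:05d}",
            rng.normal(0, np.sqrt(sigma2["breeder_f" if sex == "f" else "breeder_m"])),
        )

    pairs = [{"f": new_breeder("f"), "m": new_breeder("m")} for _ in range(n_pairs)]

    rows = []
    settle_tree = cKDTree(scene.settlements) if scene.settlements.size else None
    nest_no = 0
    for t in range(n_years):
        year = first_year + t
        for p_idx in range(n_pairs):
            if nest_no >= n_nests:
                break
            nest_no += 1
            if neighbour_lists is None:
                cell = int(rng.integers(fx.size))
            else:
                hood = neighbour_lists[p_idx] or [centers_idx[p_idx]]
                cell = hood[rng.integers(len(hood))]
            x, y = fx[cell], fy[cell]
            ud = _field_mean_in_radius(scene.understory, x, y, radius, scene.forest_mask)
            if settle_tree is None:
                raise ValueError("scene has no settlements; cannot compute distances")
            d, _ = settle_tree.query([x, y])
            close = 1.0 if d < bp else 0.0
            unmanaged = 1.0 if x >= scene.managed_split_x else 0.0
            lud = np.log(max(ud, cfg.ud_log_floor))
            (fid, uf), (mid, um) = pairs[p_idx]["f"], pairs[p_idx]["m"]
            # the truth may carry the understory effect on the log or the
            # raw percentage scale (keys log_ud/ud and their interactions)
            eta = (
                beta["intercept"]
                + beta.get("area_unmanaged", 0.0) * unmanaged
                + beta.get("close", 0.0) * close
                + beta.get("log_ud", 0.0) * lud
                + beta.get("ud", 0.0) * ud
                + beta.get("close_x_log_ud", 0.0) * close * lud
                + beta.get("close_x_ud", 0.0) * close * ud
                + u_year[t]
                + uf
                + um
            )
            rows.append(
                {
                    "id": f"N{nest_no:05d}",
                    "x": x,
                    "y": y,
                    "year": year,
                    "breeder_f": fid,
                    "breeder_m": mid,
                    "success": int(rng.random() < expit(eta)),
                    "renest_flag": False,
                    "treated_flag": False,
                    "area": "unmanaged" if unmanaged else "managed",
                    "dist_settlement": float(d),
                    "ud_nest": ud,
                }
            )
        # breeder turnover between seasons
        for p in pairs:
            for sex in ("f", "m"):
                if rng.random() > pair_persistence:
                    p[sex] = new_breeder(sex)

    df = pd.DataFrame(rows)
    if n_renest or n_treated:
        # disjoint by construction: a renest and a treatment exclusion are
        # different events in different study years
        total = min(n_renest + n_treated, len(df))
        idx = rng.choice(len(df), size=total, replace=False)
        df.loc[idx[:n_renest], "renest_flag"] = True
        df.loc[idx[n_renest:], "treated_flag"] = True
    return df


def generate_jay_observations(
    scene: SceneTruth,
    n_obs: int,
    seed: int = 0,
    distances: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bernoulli predator-presence observations along the distance gradient.

    With no explicit distances, observation sites are uniform random points
    in the scene and their distances to the nearest settlement are used,
    emulating observation bouts at nests spread over the study site.
    """
    if n_obs < 10:
        log.warning("n_obs=%d < 10: the occurrence fit will be unstable", n_obs)
    rng = rng_for(seed, "jays")
    if distances is None:
        if scene.settlements.size == 0:
            raise ValueError("scene has no settlements")
        xmin, ymin, xmax, ymax = scene.spec.extent
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, n_obs), rng.uniform(ymin, ymax, n_obs)]
        )
        d, _ = cKDTree(scene.settlements).query(pts)
    else:
        d = np.asarray(distances, dtype=float)
        d = rng.choice(d, size=n_obs, replace=True)
    a0, a1 = scene.jay_truth
    presence = (rng.random(n_obs) < expit(a0 + a1 * d)).astype(int)
    return pd.DataFrame({"distance": d, "presence": presence})


def generate_occurrence_raster(
    suitability: Raster,
    coarse_cell: float,
    noise_sd: float = 0.0,
    bias_field: np.ndarray | None = None,
    seed: int = 0,
) -> Raster:
    """Coarse occurrence-probability raster: block means + noise + bias, clipped.

    ``bias_field`` (coarse-grid array) emulates regional disagreement such
    as a climate-driven overestimation in part of the landscape.
    """
    coarse = aggregate_to_coarse(suitability, coarse_cell)
    rng = rng_for(seed, "occurrence")
    vals = coarse.values.copy()
    if noise_sd > 0:
        vals = vals + rng.normal(0, noise_sd, size=vals.shape)
    if bias_field is not None:
        bias = np.asarray(bias_field, dtype=float)
        if bias.shape != vals.shape:
            raise ValueError("bias field not congruent with the coarse grid")
        vals = vals + bias
    vals = np.clip(vals, 0.0, 1.0)
    vals[np.isnan(coarse.values)] = np.nan
    return Raster(vals, coarse.spec)


def true_density_raster(scene: SceneTruth):
    """The scene's true understory field wrapped as a fully valid density raster.

    Lets the multi-radius machinery run on noise-free ground truth, which
    isolates scale-of-effect questions from LiDAR sampling error.
    """
    from .lidar import DensityRaster

    return DensityRaster(
        density=scene.understory.copy(),
        forest_mask=scene.forest_mask.copy(),
        nodata_mask=np.zeros(scene.spec.shape, dtype=bool),
        low=scene.config.understory_low,
        high=scene.config.understory_high,
    )


def true_suitability(
    scene: SceneTruth,
    neighborhood_radius: float | None = None,
    nesting_ranges: dict[str, tuple[float, float]] | None = None,
) -> Raster:
    """Fixed-effects breeding-success probability implied by the scene truth."""
    cfg = scene.config
    radius = neighborhood_radius or cfg.nest_radius
    ud = neighborhood_mean(scene.understory, radius)
    dist = distance_raster(scene.settlements, scene.spec)
    ranges = nesting_ranges or {"close": (0.0, 100.0), "far": (0.0, 100.0)}
    return predict_suitability(
        scene.glmm_truth["beta"],
        ud,
        dist,
        scene.forest_mask,
        ranges,
        scene.true_breakpoint,
        area=scene.unmanaged_mask(),
        ud_log_floor=cfg.ud_log_floor,
    )
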