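"""The understory-density metric, height normalization and buffer summaries."""

from datetime import date

import numpy as np
import pytest

from understory_hsm.config import RunConfig
from understory_hsm.grids import GridSpec, Raster
from understory_hsm.io import LidarPointSet
from understory_hsm import lidar


def _cloud(coords):
    return LidarPointSet(np.asarray(coords, dtype=float))


def brute_force_density(points, spec, low, high):
    """Independent per-cell counting loop used as the metric oracle."""
    out = np.full(spec.shape, np.nan)
    for i in range(spec.ny):
        for j in range(spec.nx):
            x0 = spec.x0 + j * spec.cell
            y0 = spec.y0 + i * spec.cell
            inside = (
                (points.x >= x0)
                & (points.x < x0 + spec.cell)
                & (points.y >= y0)
                & (points.y < y0 + spec.cell)
            )
            total = int(inside.sum())
            if total:
                n_under = int(((points.h[inside] >= low) & (points.h[inside] < high)).sum())
                out[i, j] = 100.0 * n_under / total
    return out


class TestNormalizeHeights:
    def test_flat_dem_subtracts_constant(self):
        spec = GridSpec(0, 0, 10.0, 5, 5)
        dem = Raster(np.full((5, 5), 100.0), spec)
        pts = _cloud([[25.0, 25.0, 103.0]])
        out = lidar.normalize_heights(pts, dem)
        assert out.h[0] == pytest.approx(3.0)

    def test_point_on_dem_node_uses_node_value(self):
        spec = GridSpec(0, 0, 10.0, 3, 3)
        vals = np.arange(9, dtype=float).reshape(3, 3)
        dem = Raster(vals, spec)
        # cell centers are the interpolation nodes
        pts = _cloud([[15.0, 25.0, 10.0]])  # node (i=2? no: y=25 -> row 2) value vals[2,1]=7
        out = lidar.normalize_heights(pts, dem)
        assert out.h[0] == pytest.approx(10.0 - vals[2, 1])

    def test_matches_independent_bilinear(self, rng):
        spec = GridSpec(0, 0, 10.0, 20, 20)
        dem = Raster(rng.normal(100, 5, size=(20, 20)), spec)
        xs = rng.uniform(5.0, 194.9, 1000)
        ys = rng.uniform(5.0, 194.9, 1000)
        zs = rng.uniform(100, 130, 1000)
        out = lidar.normalize_heights(_cloud(np.column_stack([xs, ys, zs])), dem)

        # hand-coded bilinear interpolation between cell centers
        gx = (xs - 5.0) / 10.0
        gy = (ys - 5.0) / 10.0
        j0 = np.clip(np.floor(gx).astype(int), 0, 18)
        i0 = np.clip(np.floor(gy).astype(int), 0, 18)
        tx = gx - j0
        ty = gy - i0
        v = dem.values
        ground = (
            v[i0, j0] * (1 - tx) * (1 - ty)
            + v[i0, j0 + 1] * tx * (1 - ty)
            + v[i0 + 1, j0] * (1 - tx) * ty
            + v[i0 + 1, j0 + 1] * tx * ty
        )
        assert np.max(np.abs(out.h - (zs - ground))) < 1e-9

    def test_disjoint_extent_errors(self):
        spec = GridSpec(0, 0, 10.0, 3, 3)
        dem = Raster(np.zeros((3, 3)), spec)
        with pytest.raises(ValueError):
            lidar.normalize_heights(_cloud([[1000.0, 1000.0, 5.0]]), dem)


class TestDensityMetric:
    def test_textbook_cell_is_fifty_percent(self):
        spec = GridSpec(0, 0, 12.5, 1, 1)
        pts = _cloud([[5, 5, 0.2], [5, 5, 0.7], [5, 5, 3.0], [5, 5, 6.0]])
        d = lidar.understory_density_raster(pts, spec, 0.5, 5.0, np.ones((1, 1), bool))
        assert d.density.values[0, 0] == pytest.approx(50.0)

    def test_all_canopy_is_zero_percent(self):
        spec = GridSpec(0, 0, 12.5, 1, 1)
        pts = _cloud([[5, 5, 6.0], [5, 5, 12.0]])
        d = lidar.understory_density_raster(pts, spec, 0.5, 5.0, np.ones((1, 1), bool))
        assert d.density.values[0, 0] == 0.0

    def test_zero_return_forest_cell_is_nodata_not_zero(self):
        spec = GridSpec(0, 0, 12.5, 2, 1)
        pts = _cloud([[5, 5, 1.0]])  # only the west cell has a return
        d = lidar.understory_density_raster(pts, spec, 0.5, 5.0, np.ones((1, 2), bool))
        assert np.isnan(d.density.values[0, 1])
        assert d.nodata_mask[0, 1]

    def test_matches_brute_force_on_random_cloud(self, rng):
        spec = GridSpec(0, 0, 12.5, 8, 6)
        n = 2000
        pts = _cloud(
            np.column_stack(
                [rng.uniform(0, 100, n), rng.uniform(0, 75, n), rng.uniform(0, 20, n)]
            )
        )
        mask = np.ones(spec.shape, bool)
        d = lidar.understory_density_raster(pts, spec, 0.5, 5.0, mask)
        oracle = brute_force_density(pts, spec, 0.5, 5.0)
        assert np.array_equal(d.density.values, oracle, equal_nan=True)

    def test_metric_invariant_to_duplication_and_order(self, rng):
        spec = GridSpec(0, 0, 12.5, 4, 4)
        n = 500
        coords = np.column_stack(
            [rng.uniform(0, 50, n), rng.uniform(0, 50, n), rng.uniform(0, 10, n)]
        )
        mask = np.ones(spec.shape, bool)
        base = lidar.understory_density_raster(_cloud(coords), spec, 0.5, 5.0, mask)
        shuffled = coords[rng.permutation(n)]
        doubled = np.vstack([shuffled, shuffled])
        dup = lidar.understory_density_raster(_cloud(doubled), spec, 0.5, 5.0, mask)
        assert np.array_equal(base.density.values, dup.density.values, equal_nan=True)

    def test_strata_fractions_sum_to_hundred(self, rng):
        spec = GridSpec(0, 0, 12.5, 4, 4)
        n = 1000
        pts = _cloud(
            np.column_stack(
                [rng.uniform(0, 50, n), rng.uniform(0, 50, n), rng.uniform(0, 20, n)]
            )
        )
        mask = np.ones(spec.shape, bool)
        below = lidar.understory_density_raster(pts, spec, 0.0, 0.5, mask).density.values
        mid = lidar.understory_density_raster(pts, spec, 0.5, 5.0, mask).density.values
        above = lidar.understory_density_raster(pts, spec, 5.0, np.inf, mask).density.values
        total = below + mid + above
        assert np.allclose(total[np.isfinite(total)], 100.0)

    def test_management_disqualification_rules(self):
        spec = GridSpec(0, 0, 12.5, 4, 1)
        pts = _cloud([[x, 5, 1.0] for x in (5, 18, 30, 43)])
        mask = np.ones((1, 4), bool)
        acq = date(2010, 9, 29)
        events = [
            lidar.ManagementEvent("clearcut", date(2005, 1, 1), (0.0, 0.0, 12.5, 12.5)),
            lidar.ManagementEvent("clearcut", date(2012, 1, 1), (12.5, 0.0, 25.0, 12.5)),
            lidar.ManagementEvent("thinning", date(2012, 1, 1), (25.0, 0.0, 37.5, 12.5)),
        ]
        d = lidar.understory_density_raster(
            pts, spec, 0.5, 5.0, mask, management_events=events, acquisition=acq
        )
        # clear-cut before acquisition -> nodata; after -> kept; thinning any date -> nodata
        assert d.nodata_mask[0, 0]
        assert not d.nodata_mask[0, 1]
        assert d.nodata_mask[0, 2]
        assert not d.nodata_mask[0, 3]


def _uniform_density_raster(value, nx=60, ny=60, cell=12.5):
    spec = GridSpec(0, 0, cell, nx, ny)
    return lidar.DensityRaster(
        density=Raster(np.full((ny, nx), float(value)), spec),
        forest_mask=np.ones((ny, nx), bool),
        nodata_mask=np.zeros((ny, nx), bool),
    )


class TestRadialSummary:
    def test_uniform_raster_any_radius(self):
        d = _uniform_density_raster(20.0)
        mean, cover, nd, valid = lidar.radial_summary(d, (375.0, 375.0), 100.0)
        assert mean == pytest.approx(20.0)
        assert cover == 1.0 and nd == 0.0 and valid

    def test_five_percent_nodata_rule(self):
        d = _uniform_density_raster(10.0, nx=30, ny=30)
        # make 2 nodata cells among the ~30 members of a 35 m buffer
        d.nodata_mask[15, 15] = d.nodata_mask[15, 16] = True
        d.density.values[15, 15] = d.density.values[15, 16] = np.nan
        center = (15 * 12.5 + 6.25, 15 * 12.5 + 6.25)
        mean, cover, nd, valid = lidar.radial_summary(d, center, 35.0)
        assert nd > 0.05
        assert not valid

    def test_matches_brute_force_mean(self, rng):
        spec = GridSpec(0, 0, 12.5, 40, 40)
        vals = rng.uniform(0, 100, size=(40, 40))
        d = lidar.DensityRaster(
            density=Raster(vals.copy(), spec),
            forest_mask=np.ones((40, 40), bool),
            nodata_mask=np.zeros((40, 40), bool),
        )
        center = (251.0, 207.0)
        mean, *_ = lidar.radial_summary(d, center, 80.0)
        xs, ys = spec.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        member = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 <= 80.0**2
        assert abs(mean - vals[member].mean()) < 1e-12

    def test_radius_below_cell_size_rejected(self):
        d = _uniform_density_raster(5.0)
        with pytest.raises(ValueError):
            lidar.radial_summary(d, (100.0, 100.0), 5.0)


class TestRadiusSeries:
    def test_constant_field_gives_flat_profile(self, config):
        d = _uniform_density_raster(17.0, nx=90, ny=90)
        prof = lidar.radius_series(d, (560.0, 560.0), config)
        assert prof.radii[0] == 15.0 and prof.radii[-1] == 460.0
        assert prof.radii.size == 101
        assert np.allclose(prof.mean_ud, 17.0)
        assert prof.valid.all()

    def test_increasing_field_gives_increasing_profile(self, config):
        spec = GridSpec(0, 0, 12.5, 90, 90)
        xs, ys = spec.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        center = (560.0, 560.0)
        dist = np.hypot(gx - center[0], gy - center[1])
        d = lidar.DensityRaster(
            density=Raster(dist / dist.max() * 80.0, spec),
            forest_mask=np.ones((90, 90), bool),
            nodata_mask=np.zeros((90, 90), bool),
        )
        prof = lidar.radius_series(d, center, config)
        assert np.all(np.diff(prof.mean_ud) > 0)
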