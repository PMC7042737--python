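"""Statistical properties and determinism of the scene generators."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency

from understory_hsm import synth
from understory_hsm.config import RunConfig
from understory_hsm.grids import GridSpec, Raster
from understory_hsm.lidar import understory_density_raster


class TestLandscape:
    def test_same_seed_bit_identical(self):
        a = synth.generate_landscape((2000.0, 2000.0), seed=3)
        b = synth.generate_landscape((2000.0, 2000.0), seed=3)
        assert np.array_equal(a.understory.values, b.understory.values)
        assert np.array_equal(a.settlements, b.settlements)
        assert np.array_equal(a.forest_mask, b.forest_mask)

    def test_zero_range_is_spatially_white(self):
        smooth = synth.generate_landscape((2000.0, 2000.0), seed=4, corr_range=100.0)
        white = synth.generate_landscape((2000.0, 2000.0), seed=4, corr_range=0.0)

        def lag1_corr(f):
            v = f.understory.values
            return np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]

        assert lag1_corr(white) < 0.2
        assert lag1_corr(smooth) > 0.8

    def test_settlement_counts_follow_poisson_moments(self):
        intensity, area_km2 = 5.0, 4.0
        counts = [
            len(
                synth.generate_landscape(
                    (2000.0, 2000.0), seed=s, settlement_intensity=intensity
                ).settlements
            )
            for s in range(100)
        ]
        expected = intensity * area_km2
        se_mean = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 3 * se_mean

    def test_field_bounds_and_extent_guard(self):
        scene = synth.generate_landscape((2000.0, 2000.0), seed=5, sd_ud=30.0)
        v = scene.understory.values
        assert v.min() >= 0.0 and v.max() <= 100.0
        with pytest.raises(ValueError):
            synth.generate_landscape((500.0, 500.0), seed=1)


class TestPointCloud:
    def test_empty_understory_field_has_no_stratum_returns(self, config):
        spec = GridSpec(0, 0, 12.5, 8, 8)
        field = Raster(np.zeros((8, 8)), spec)
        pts = synth.generate_point_cloud(field, np.ones((8, 8), bool), 1.0, seed=1)
        assert not np.any((pts.h >= 0.5) & (pts.h < 5.0))

    def test_full_field_no_ground_all_in_stratum(self):
        spec = GridSpec(0, 0, 12.5, 8, 8)
        field = Raster(np.full((8, 8), 100.0), spec)
        pts = synth.generate_point_cloud(
            field, np.ones((8, 8), bool), 1.0, seed=2, ground_fraction=0.0
        )
        assert np.all((pts.h >= 0.5) & (pts.h < 5.0))

    def test_metric_recovers_generating_density(self, config):
        """Generator/metric consistency: rasterized cloud gives back the field."""
        spec = GridSpec(0, 0, 12.5, 20, 20)
        field = Raster(np.full((20, 20), 30.0), spec)
        mask = np.ones((20, 20), bool)
        pts = synth.generate_point_cloud(field, mask, 1.0, seed=3)
        dens = understory_density_raster(pts, spec, 0.5, 5.0, mask)
        vals = dens.density.values[np.isfinite(dens.density.values)]
        # cell-level deviations stay within binomial error, and the scene
        # mean is tight: SE of the mean ~ sqrt(30*70/156)/20 ~ 0.2
        assert abs(vals.mean() - 30.0) < 3 * 0.25
        lam = 1.0 * 12.5**2
        binom_se = 100 * np.sqrt(0.3 * 0.7 / lam)
        assert np.quantile(np.abs(vals - 30.0), 0.99) < 4 * binom_se

    def test_pulse_density_bounds(self, small_scene):
        with pytest.raises(ValueError):
            synth.generate_point_cloud(
                small_scene.understory, small_scene.forest_mask, 0.01
            )


class TestNests:
    def test_null_truth_gives_half_success(self):
        truth = {
            "beta": {k: 0.0 for k in synth.DEFAULT_GLMM_TRUTH["beta"]},
            "sigma2": {"year": 0.0, "breeder_f": 0.0, "breeder_m": 0.0},
        }
        scene = synth.generate_landscape(
            (3000.0, 3000.0), seed=6, settlement_intensity=1.0, glmm_truth=truth
        )
        df = synth.generate_nests(scene, n_nests=2000, seed=7)
        se = 0.5 / np.sqrt(2000)
        assert abs(df["success"].mean() - 0.5) < 3 * se

    def test_same_seed_identical_outcomes(self, small_scene):
        a = synth.generate_nests(small_scene, 200, seed=8)
        b = synth.generate_nests(small_scene, 200, seed=8)
        assert a["success"].tolist() == b["success"].tolist()
        assert a["breeder_f"].tolist() == b["breeder_f"].tolist()

    def test_interaction_reverses_proximity_effect_across_density(self):
        """With the generating interaction, being close to settlements helps
        at low understory density and hurts at high density (sign check on
        the generating model itself)."""
        b = synth.DEFAULT_GLMM_TRUTH["beta"]

        def eta(close, ud):
            lud = np.log(ud)
            return b["intercept"] + b["close"] * close + b["log_ud"] * lud \
                + b["close_x_log_ud"] * close * lud

        # close helps below the reversal density exp(1.04/1.57) ~ 1.9%
        low, high = 1.0, 25.0
        assert eta(1, low) > eta(0, low)
        assert eta(1, high) < eta(0, high)

        # and the simulated outcomes reproduce the reversal at large n
        scene = synth.generate_landscape(
            (6000.0, 6000.0), seed=9, settlement_intensity=0.25, corr_range=30.0,
            mean_ud=7.0, sd_ud=6.0,
        )
        df = synth.generate_nests(scene, 8000, seed=10, territory_jitter=np.inf)
        close = df.dist_settlement < scene.true_breakpoint
        lowud = df.ud_nest < 1.5
        highud = df.ud_nest > 12.0
        if min((close & lowud).sum(), (~close & lowud).sum()) > 50:
            assert df.success[close & lowud].mean() > df.success[~close & lowud].mean()
        if min((close & highud).sum(), (~close & highud).sum()) > 50:
            assert df.success[close & highud].mean() < df.success[~close & highud].mean()

    def test_breeders_persist_across_years(self, small_scene):
        df = synth.generate_nests(small_scene, 300, n_years=10, pair_persistence=0.9, seed=11)
        # with persistence 0.9 most breeders appear in several seasons
        counts = df.groupby("breeder_f")["year"].nunique()
        assert counts.max() > 3
        assert df.breeder_f.nunique() < 300 / 2

    def test_nests_only_on_forest_cells(self, small_scene):
        df = synth.generate_nests(small_scene, 150, seed=12)
        spec = small_scene.spec
        i, j = spec.index_of(df["x"].to_numpy(), df["y"].to_numpy())
        assert small_scene.forest_mask[i, j].all()


class TestJays:
    def test_presence_is_binary_and_depends_on_distance(self, small_scene):
        obs = synth.generate_jay_observations(small_scene, 3000, seed=13)
        assert set(obs["presence"].unique()) <= {0, 1}
        near = obs[obs.distance < 800]["presence"].mean()
        far = obs[obs.distance > 2000]["presence"].mean()
        if np.isfinite(near) and np.isfinite(far):
            assert near > far

    def test_flat_truth_gives_distance_independence(self):
        scene = synth.generate_landscape(
            (3000.0, 3000.0), seed=14, settlement_intensity=1.0, jay_truth=(0.5, 0.0)
        )
        obs = synth.generate_jay_observations(scene, 2000, seed=15)
        bins = np.digitize(obs.distance, np.quantile(obs.distance, [0.25, 0.5, 0.75]))
        table = np.array(
            [[(obs.presence[bins == b] == v).sum() for v in (0, 1)] for b in range(4)]
        )
        assert chi2_contingency(table)[1] > 0.01


class TestOccurrenceRaster:
    def test_noise_free_equals_block_means(self, small_scene):
        suit = synth.true_suitability(small_scene)
        occ = synth.generate_occurrence_raster(suit, 500.0, noise_sd=0.0, seed=16)
        from understory_hsm.landscape import aggregate_to_coarse

        ref = aggregate_to_coarse(suit, 500.0)
        ok = np.isfinite(ref.values)
        assert np.allclose(occ.values[ok], np.clip(ref.values[ok], 0, 1))

    def test_values_clipped_to_unit_interval(self, small_scene):
        suit = synth.true_suitability(small_scene)
        occ = synth.generate_occurrence_raster(suit, 500.0, noise_sd=0.5, seed=17)
        v = occ.values[np.isfinite(occ.values)]
        assert v.min() >= 0.0 and v.max() <= 1.0
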