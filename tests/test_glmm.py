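"""The Laplace mixed-model fitter, closed forms, and model-selection scans."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from understory_hsm.config import RunConfig
from understory_hsm import glmm, synth


def _toy_single_factor(n=30, q=3, sigma=0.8, seed=5):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, q, n)
    u = rng.normal(0, sigma, q)
    x = rng.normal(size=n)
    eta = 0.3 + 0.7 * x + u[g]
    y = (rng.random(n) < expit(eta)).astype(float)
    X = np.column_stack([np.ones(n), x])
    return y, X, g


def gauss_hermite_loglik(y, X, g, beta, sigma, nodes=50):
    """Independent marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    With a single random factor the likelihood factorizes over levels; each
    one-dimensional integral is centered on the conditional mode with the
    conditional curvature (the 'adaptive' part).
    """
    t, w = np.polynomial.hermite.hermgauss(nodes)
    ll = 0.0
    for lev in np.unique(g):
        idx = g == lev
        eta0 = X[idx] @ beta

        def neg_joint(u):
            e = eta0 + u
            return -(np.sum(y[idx] * e - np.logaddexp(0, e)) - 0.5 * u**2 / sigma**2)

        # locate the conditional mode by a tiny Newton iteration
        u_hat = 0.0
        for _ in range(50):
            mu = expit(eta0 + u_hat)
            grad = np.sum(y[idx] - mu) - u_hat / sigma**2
            hess = -np.sum(mu * (1 - mu)) - 1 / sigma**2
            step = grad / hess
            u_hat -= step
            if abs(step) < 1e-12:
                break
        s_hat = 1.0 / np.sqrt(-hess)
        u_nodes = u_hat + np.sqrt(2.0) * s_hat * t
        e = eta0[None, :] + u_nodes[:, None]
        log_f = (
            np.sum(y[idx] * e - np.logaddexp(0, e), axis=1)
            - 0.5 * u_nodes**2 / sigma**2
            - 0.5 * np.log(2 * np.pi * sigma**2)
        )
        log_int = np.log(np.sqrt(2.0) * s_hat) + np.logaddexp.reduce(
            np.log(w) + t**2 + log_f
        )
        ll += log_int
    return float(ll)


class TestLaplaceCore:
    def test_laplace_close_to_quadrature_on_toy(self):
        y, X, g = _toy_single_factor()
        beta = np.array([0.3, 0.7])
        sigma = 0.8
        lap = glmm.laplace_loglik(y, X, {"g": g}, beta, [sigma])
        agq = gauss_hermite_loglik(y, X, g, beta, sigma)
        assert abs(lap - agq) < 0.05

    def test_zero_variance_truth_collapses_to_plain_logistic(self):
        rng = np.random.default_rng(11)
        n = 600
        x = rng.normal(size=n)
        eta = -0.2 + 0.9 * x
        y = (rng.random(n) < expit(eta)).astype(float)
        X = np.column_stack([np.ones(n), x])
        g = {"grp": rng.integers(0, 12, n)}
        fit = glmm.fit_mixed_logit(y, X, ["int", "x"], g)
        import statsmodels.api as sm

        plain = sm.Logit(y, X).fit(disp=0)
        assert abs(fit.beta[1] - plain.params[1]) < 2 * plain.bse[1]
        assert sum(fit.sigma2.values()) < 0.2

    def test_matches_lme4_glmer_on_crossed_design(self, tmp_path):
        """Independent oracle: R's glmer on the same data, same Laplace ML."""
        scene = synth.generate_landscape(
            (6000.0, 6000.0), seed=21, settlement_intensity=0.2
        )
        df = synth.generate_nests(scene, n_nests=400, n_years=8, seed=22)
        close = df.dist_settlement < 1450
        assert 50 < close.sum() < 350  # both proximity classes present
        fit = glmm.fit_breeding_model(df, 1450.0)

        d = df.copy()
        d["close"] = (d.dist_settlement < 1450).astype(int)
        d["lud"] = np.log(np.maximum(d.ud_nest, 0.1))
        d["unmanaged"] = (d.area == "unmanaged").astype(int)
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(success ~ unmanaged + close*lud + (1|year) + (1|breeder_f)
                       + (1|breeder_m), data=d, family=binomial)
            cat(fixef(m), as.numeric(logLik(m)), sep="\\n")
            """
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        vals = [float(v) for v in out.stdout.strip().splitlines()[-6:]]
        ref_beta, ref_ll = np.array(vals[:5]), vals[5]
        assert np.max(np.abs(fit.beta - ref_beta)) < 0.03
        assert abs(fit.loglik - ref_ll) < 0.02

    def test_nested_likelihood_never_decreases_with_true_effect(self):
        scene = synth.generate_landscape(
            (4000.0, 4000.0), seed=31, settlement_intensity=0.5
        )
        df = synth.generate_nests(scene, n_nests=500, n_years=8, seed=32)
        full = glmm.fit_breeding_model(df, 1450.0)
        y, X, terms, groups = glmm.build_design(df, 1450.0)
        reduced = glmm.fit_mixed_logit(y, X[:, :3], terms[:3], groups)
        assert full.loglik >= reduced.loglik - 1e-6


class TestClosedForms:
    def test_aicc_printed_example(self):
        assert glmm.aicc(-100.0, 5, 235) == pytest.approx(210.0 + 60.0 / 229.0, abs=1e-12)

    def test_aicc_approaches_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 5
        assert glmm.aicc(-100.0, 5, 10**9) == pytest.approx(aic, abs=1e-6)
        with pytest.raises(ValueError):
            glmm.aicc(-100.0, 5, 6)

    def test_aicc_matches_formula_on_random_triples(self, rng):
        for _ in range(20):
            ll = rng.uniform(-500, -10)
            k = int(rng.integers(1, 12))
            n = int(rng.integers(k + 2, 1000))
            expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert glmm.aicc(ll, k, n) == pytest.approx(expected, abs=1e-9)

    def test_r2_glmm_formula_case(self):
        fit = glmm.MixedLogitFit(
            terms=["x"], beta=np.array([1.0]), se=np.array([0.1]),
            sigma2={"g": 1.0}, loglik=-10.0, n=50, k=2, converged=True,
            fixed_linpred=np.array([0.0, 2.0] * 25),  # variance exactly 1
            X=np.zeros((50, 1)), y=np.zeros(50),
        )
        r2m, r2c = glmm.r2_glmm(fit)
        denom = 2.0 + np.pi**2 / 3.0
        assert r2m == pytest.approx(1.0 / denom, abs=1e-12)
        assert r2c == pytest.approx(2.0 / denom, abs=1e-12)

    def test_r2_zero_for_constant_fixed_predictor(self):
        fit = glmm.MixedLogitFit(
            terms=["i"], beta=np.array([0.3]), se=np.array([0.1]),
            sigma2={"g": 0.5}, loglik=-10.0, n=20, k=2, converged=True,
            fixed_linpred=np.full(20, 0.3), X=np.zeros((20, 1)), y=np.zeros(20),
        )
        assert glmm.r2_glmm(fit)[0] == pytest.approx(0.0, abs=1e-12)

    def test_vif_orthogonal_columns_are_one(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        out = glmm.vif(X, ["int", "a", "b"])
        assert out["a"] == pytest.approx(1.0, abs=0.05)

    def test_vif_duplicate_column_is_infinite(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, x])
        out = glmm.vif(X, ["int", "a", "a_copy"])
        assert np.isinf(out["a"])

    def test_vif_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        n = 300
        z = rng.normal(size=n)
        X = np.column_stack(
            [np.ones(n), z + 0.5 * rng.normal(size=n), z + 0.5 * rng.normal(size=n),
             rng.normal(size=n)]
        )
        ours = glmm.vif(X, ["int", "a", "b", "c"])
        for j, name in ((1, "a"), (2, "b"), (3, "c")):
            ref = variance_inflation_factor(X, j)
            assert ours[name] == pytest.approx(ref, rel=1e-10)


@pytest.fixture(scope="module")
def log_effect_data():
    scene = synth.generate_landscape(
        (6000.0, 6000.0), seed=41, settlement_intensity=0.3
    )
    return synth.generate_nests(scene, n_nests=3000, n_years=12, seed=42)


class TestSelectionProcedures:

    def test_log_transform_wins_on_log_generated_data(self, log_effect_data):
        table = glmm.transform_selection(log_effect_data, 1450.0)
        assert table.loc[0, "transform"] == "log"
        assert (table["n"] == table["n"].iloc[0]).all()

    def test_breakpoint_scan_recovers_truth_and_keeps_grid_discipline(self, log_effect_data):
        cfg = RunConfig()
        best, table = glmm.breakpoint_scan(log_effect_data, cfg)
        assert abs(best - 1450.0) <= 50.0
        steps = np.diff(table["breakpoint"].to_numpy())
        assert np.allclose(steps, 50.0)
        dist = log_effect_data["dist_settlement"]
        assert table["breakpoint"].min() >= np.percentile(dist, 10) - 50.0
        assert table["breakpoint"].max() <= np.percentile(dist, 90) + 50.0

    def test_scan_skips_tiny_classes(self):
        scene = synth.generate_landscape(
            (4000.0, 4000.0), seed=51, settlement_intensity=0.5
        )
        df = synth.generate_nests(scene, n_nests=300, n_years=8, seed=52)
        _, table = glmm.breakpoint_scan(df, min_class_size=140)
        assert table["skipped"].any()

    def test_sensitivity_flags_null_interaction(self):
        truth = {
            "beta": {"intercept": 0.1, "area_unmanaged": 0.0, "close": 0.0,
                     "log_ud": 0.0, "close_x_log_ud": 0.0},
            "sigma2": {"year": 0.2, "breeder_f": 0.2, "breeder_m": 0.2},
        }
        scene = synth.generate_landscape(
            (5000.0, 5000.0), seed=61, settlement_intensity=0.4, glmm_truth=truth
        )
        df = synth.generate_nests(scene, n_nests=500, n_years=8, seed=62)
        table = glmm.breakpoint_sensitivity(df, 1350.0, 1550.0)
        assert len(table) == 5  # one row per candidate
        assert table["crosses_zero"].mean() > 0.5

    def test_strong_interaction_keeps_sign_near_truth(self, log_effect_data):
        table = glmm.breakpoint_sensitivity(log_effect_data, 1350.0, 1650.0)
        assert not table["crosses_zero"].any()
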