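"""Penalized additive trend models and residual spatial autocorrelation."""

import numpy as np
import pandas as pd
import pytest

from saprocom.synthetic import SimulationConfig, simulate_dataset
from saprocom.trends import (build_trend_frame, fit_additive_model,
                             fit_richness_model, morans_i_residuals,
                             significance_stars)


def make_frame(n_per_group=60, seed=0, years=8):
    """Balanced model frame over the three tree species with coordinates."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("spruce", "fir", "beech"):
        for i in range(n_per_group):
            rows.append({
                "tree_species": g,
                "exposure_year": float(rng.integers(1, years + 1)),
                "E": rng.uniform(0, 1000),
                "N": rng.uniform(0, 1000),
            })
    return pd.DataFrame(rows)


class TestGaussianFit:
    def test_constant_response_shrinks_to_flat(self):
        df = make_frame(40, seed=1)
        df["y"] = 3.0
        fit = fit_additive_model(df, "y", family="gaussian", k_year=6,
                                 n_knots_spatial=6)
        np.testing.assert_allclose(fit.fitted, 3.0, atol=1e-6)
        assert fit.adj_r2 == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_smooth_near_perfect_r2(self):
        df = make_frame(60, seed=2)
        df["y"] = np.sin(df["exposure_year"]) + 0.25 * df["exposure_year"]
        fit = fit_additive_model(df, "y", family="gaussian", k_year=8,
                                 n_knots_spatial=0)
        assert fit.adj_r2 >= 0.99

    def test_unpenalized_gaussian_matches_ols_oracle(self):
        """With lambda -> 0 the fit equals ordinary least squares."""
        df = make_frame(50, seed=3)
        rng = np.random.default_rng(3)
        df["y"] = df["exposure_year"] + rng.normal(size=len(df))
        fit = fit_additive_model(df, "y", family="gaussian", k_year=5,
                                 n_knots_spatial=0, optimize_lambda=False,
                                 lam_init=np.full(3, 1e-12))
        X = fit.design.X
        beta_ols, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(X @ fit.coef, X @ beta_ols, atol=1e-5)

    def test_heavy_penalty_reduces_edf(self):
        df = make_frame(50, seed=4)
        rng = np.random.default_rng(4)
        df["y"] = np.sin(df["exposure_year"]) + rng.normal(scale=0.2,
                                                           size=len(df))
        lo = fit_additive_model(df, "y", family="gaussian", k_year=8,
                                n_knots_spatial=0, optimize_lambda=False,
                                lam_init=np.full(3, 1e-6))
        hi = fit_additive_model(df, "y", family="gaussian", k_year=8,
                                n_knots_spatial=0, optimize_lambda=False,
                                lam_init=np.full(3, 1e8))
        for term in lo.edf_by_term:
            if term.startswith("s(year)"):
                assert hi.edf_by_term[term] <= lo.edf_by_term[term] + 1e-6
        assert hi.edf_total < lo.edf_total


class TestNegativeBinomialFit:
    def test_recovers_declining_abundance_smooth(self):
        """Fitted curve tracks a known exponential decline, corr >= 0.95."""
        rng = np.random.default_rng(5)
        df = make_frame(45, seed=5)  # n = 135 sites x years rows
        truth = np.exp(2.0 - 0.3 * df["exposure_year"].to_numpy())
        theta = 3.0
        y = rng.negative_binomial(theta, theta / (theta + truth))
        df["y"] = y
        fit = fit_additive_model(df, "y", family="negative_binomial",
                                 k_year=6, n_knots_spatial=0)
        corr = np.corrcoef(fit.fitted, truth)[0, 1]
        assert corr >= 0.95

    def test_non_integer_counts_rejected(self):
        df = make_frame(10, seed=6)
        df["y"] = 1.5
        with pytest.raises(ValueError, match="integer"):
            fit_additive_model(df, "y", family="negative_binomial")

    def test_prediction_bands_positive_on_count_scale(self):
        rng = np.random.default_rng(7)
        df = make_frame(30, seed=7)
        df["y"] = rng.poisson(5.0, size=len(df))
        fit = fit_additive_model(df, "y", family="negative_binomial",
                                 k_year=5, n_knots_spatial=4)
        grid = fit.prediction_grid(df, n_points=10)
        assert (grid["lower"] > 0).all()
        assert (grid["lower"] <= grid["fit"]).all()
        assert (grid["fit"] <= grid["upper"]).all()


class TestRichnessModel:
    def test_abundance_coefficient_near_one_when_proportional(self):
        """log-link proportionality: S ~ N implies coef(log N) ~ 1."""
        rng = np.random.default_rng(8)
        df = make_frame(50, seed=8)
        df["abundance"] = rng.integers(5, 500, size=len(df))
        lam = 0.3 * df["abundance"].to_numpy()
        df["n_species"] = rng.poisson(lam)
        df = df[df["n_species"] > 0]
        fit = fit_richness_model(df, k_year=5, n_knots_spatial=0)
        names = [t.name for t in fit.design.terms]
        i = names.index("log_abundance")
        sl = fit.design.terms[i].cols
        assert fit.coef[sl][0] == pytest.approx(1.0, abs=0.1)

    def test_zero_abundance_rows_excluded(self):
        rng = np.random.default_rng(9)
        df = make_frame(20, seed=9)
        df["abundance"] = rng.integers(0, 30, size=len(df))
        df["n_species"] = rng.poisson(3.0, size=len(df))
        fit = fit_richness_model(df, k_year=5, n_knots_spatial=0)
        assert len(fit.y) == int((df["abundance"] > 0).sum())

    def test_injected_u_shape_detected(self):
        """A planted U-shaped year effect in one tree species is significant."""
        rng = np.random.default_rng(10)
        df = make_frame(60, seed=10)
        df["abundance"] = rng.integers(20, 200, size=len(df))
        eta = 0.6 * np.log(df["abundance"].to_numpy())
        u = np.where(df["tree_species"] == "spruce",
                     0.35 * (df["exposure_year"] - 4.5) ** 2, 0.0)
        df["n_species"] = rng.poisson(np.exp(eta + u - 1.0))
        df = df[df["n_species"] > 0]
        fit = fit_richness_model(df, k_year=6, n_knots_spatial=0)
        assert fit.smooth_pvalues["s(year):spruce"] < 0.01
        assert fit.edf_by_term["s(year):spruce"] > 1.5


class TestTrendFrame:
    def test_aggregates_per_log_year(self, small_dataset):
        _, _, _, design, community, _ = small_dataset
        frame = build_trend_frame(community, design)
        row = frame.iloc[0]
        asm = community.assemblage(row["log_id"], row["exposure_year"])
        assert row["abundance"] == sum(asm.values())
        assert row["n_species"] == len(asm)
        assert set(frame.columns) >= {"abundance", "n_species", "tree_species",
                                      "E", "N"}


class TestMoransI:
    def test_null_calibration(self):
        """i.i.d. residuals: E[I] = -1/(n-1) and ~5% rejections at alpha=.05."""
        rng = np.random.default_rng(11)
        n = 25
        coords = rng.uniform(0, 100, size=(n, 2))
        stats_i, rejections = [], 0
        n_sim = 400
        for _ in range(n_sim):
            res = morans_i_residuals(rng.normal(size=n), coords)
            stats_i.append(res.I)
            rejections += res.p_value < 0.05
        assert np.mean(stats_i) == pytest.approx(-1.0 / (n - 1), abs=0.02)
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_detects_linear_gradient(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 100, size=(40, 2))
        resid = 0.05 * coords[:, 0] + rng.normal(scale=0.1, size=40)
        res = morans_i_residuals(resid, coords)
        assert res.I > 0
        assert res.p_value < 0.01

    def test_two_locations_rejected(self):
        with pytest.raises(ValueError, match="3 unique"):
            morans_i_residuals(np.array([1.0, -1.0]),
                               np.array([[0, 0], [1, 1]]))

    def test_repeated_coordinates_averaged(self):
        coords = np.array([[0, 0], [0, 0], [10, 0], [0, 10]])
        res = morans_i_residuals(np.array([1.0, 3.0, 0.5, -0.5]), coords)
        assert res.n_locations == 3


def test_significance_star_convention():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.02) == "*"
    assert significance_stars(0.07) == "."
    assert significance_stars(0.5) == ""
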