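import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import georisk as g
from georisk.geostat import (MCSettings, ParamSet, cov_matrix,
                             sample_latent_field)

from conftest import BITE_BETA, ENV_BETA


class TestExponentialCov:
    def test_at_zero(self):
        assert g.exponential_cov(0.0, 0.5, 2.0) == pytest.approx(0.5)

    def test_at_range(self):
        assert g.exponential_cov(2.0, 1.0, 2.0) == pytest.approx(
            np.exp(-1), abs=1e-4)

    def test_monotone_decay(self):
        u = np.linspace(0, 100, 50)
        c = g.exponential_cov(u, 1.0, 3.0)
        assert np.all(np.diff(c) < 0)
        assert c[-1] < 1e-10

    def test_bad_params(self):
        with pytest.raises(ValueError):
            g.exponential_cov(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            g.exponential_cov(1.0, -1.0, 1.0)

    @given(st.integers(2, 25), st.floats(0.01, 10.0), st.floats(0.1, 50.0),
           st.floats(0.0, 5.0), st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_cov_matrix_psd(self, m, sigma2, phi, tau2, seed):
        coords = np.random.default_rng(seed).uniform(0, 100, (m, 2))
        cov = cov_matrix(coords, sigma2, phi, tau2)
        np.testing.assert_allclose(cov, cov.T)
        eigvals = np.linalg.eigvalsh(cov)
        assert eigvals.min() > -1e-8


class TestLinearPredictor:
    def _loc(self, elevation, zone, density, agri):
        return pd.DataFrame({
            "elevation": [elevation], "population_density": [density],
            "agri_proportion": [agri], "climate_zone": [zone],
        })

    def test_bite_model_baseline(self):
        # dry zone, sea level, empty cell: intercept only
        eta = g.linear_predictor(self._loc(0.0, "dry", 0.0, 0.0), BITE_BETA,
                                 g.bite_model_spec())
        assert eta[0] == pytest.approx(-6.6239)
        assert 1e5 * np.exp(eta[0]) == pytest.approx(132.8, abs=0.1)

    def test_bite_model_wet_hillside(self):
        # elevation at the knot, wet zone, 9% agricultural workers
        eta = g.linear_predictor(self._loc(160.0, "wet", 0.0, 0.09),
                                 BITE_BETA, g.bite_model_spec())
        expected = -6.6239 + 0.0032 * 160 + 0.5586 + 7.2235 * 0.09
        assert eta[0] == pytest.approx(expected, abs=1e-10)
        assert 1e5 * np.exp(eta[0]) == pytest.approx(742.0, abs=1.0)

    def test_envenoming_baseline(self):
        eta = g.linear_predictor(self._loc(0.0, "dry", 0.0, 0.0), ENV_BETA,
                                 g.envenoming_model_spec())
        assert 1e5 * np.exp(eta[0]) == pytest.approx(226.0, abs=0.5)

    def test_missing_covariate_flagged(self):
        df = self._loc(0.0, "dry", 0.0, 0.0)
        df.loc[0, "elevation"] = np.nan
        eta = g.linear_predictor(df, BITE_BETA, g.bite_model_spec())
        assert np.isnan(eta[0])

    def test_wrong_beta_length(self):
        with pytest.raises(ValueError, match="entries"):
            g.linear_predictor(self._loc(0, "dry", 0, 0), np.zeros(3),
                               g.bite_model_spec())


class TestSampleLatentField:
    def test_degenerate_prior_collapses(self, glm_survey, simple_spec):
        _, clusters = glm_survey
        params = ParamSet(np.array([-5.5, 0.0005, 0.2, 0.5]), 0.0, 1.0, 0.0)
        samples = sample_latent_field(clusters, simple_spec, params,
                                      MCSettings(n_burn=5, thin=1, n_keep=20),
                                      seed=0)
        assert np.allclose(samples.draws, 0.0)

    def test_deterministic(self, spatial_survey):
        truth, _, clusters = spatial_survey
        params = ParamSet(truth.beta, truth.sigma2, truth.phi, truth.tau2)
        st_ = MCSettings(n_burn=100, thin=2, n_keep=50)
        a = sample_latent_field(clusters, truth.spec, params, st_, seed=4)
        b = sample_latent_field(clusters, truth.spec, params, st_, seed=4)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_laplace_oracle_large_counts(self):
        # single cluster, large count: posterior ~ Gaussian at the
        # Newton mode of log p(W | y)
        cl = pd.DataFrame({
            "cluster_id": ["c1"], "x_km": [0.0], "y_km": [0.0],
            "n_sampled": [100_000], "y_bites": [500],
            "elevation": [0.0], "population_density": [0.0],
            "agri_proportion": [0.0], "climate_zone": ["dry"],
            "stratum": ["s1"],
        })
        spec = g.ModelSpec("y_bites", ())
        beta0 = np.log(400 / 100_000)
        params = ParamSet(np.array([beta0]), 0.3, 1.0, 0.0)
        samples = sample_latent_field(
            cl, spec, params, MCSettings(n_burn=500, thin=2, n_keep=1000),
            seed=3)
        # Laplace mode: maximize -w^2/(2*0.3) + y*w - n*exp(beta0)*exp(w)
        from scipy.optimize import minimize_scalar
        neg = lambda w: w ** 2 / 0.6 - 500 * w + 400 * np.exp(w)
        mode = minimize_scalar(neg, bounds=(-2, 2), method="bounded").x
        mc_se = samples.draws.std() / np.sqrt(len(samples.draws) / 10)
        assert abs(samples.draws.mean() - mode) < 3 * mc_se + 1e-3

    def test_acceptance_rate_reported(self, spatial_survey):
        truth, _, clusters = spatial_survey
        params = ParamSet(truth.beta, truth.sigma2, truth.phi, truth.tau2)
        samples = sample_latent_field(
            clusters, truth.spec, params,
            MCSettings(n_burn=300, thin=2, n_keep=100), seed=9)
        assert 0.1 <= samples.acceptance_rate <= 0.9


class TestFitMCML:
    def test_glm_limit(self, glm_survey, simple_spec):
        _, clusters = glm_survey
        glm = g.fit_glm(clusters, simple_spec)
        init = ParamSet(np.zeros(4), 0.0, 1.0, 0.0)
        fit = g.fit_mcml(clusters, simple_spec, init=init,
                         settings=MCSettings(n_burn=10, thin=1, n_keep=50),
                         seed=1, fix_covariance=True)
        np.testing.assert_allclose(fit.params.beta, glm.params, atol=5e-4)

    def test_ascent_property(self, spatial_survey):
        truth, _, clusters = spatial_survey
        fit = g.fit_mcml(clusters, truth.spec,
                         settings=MCSettings(n_burn=400, thin=2, n_keep=200),
                         seed=2)
        assert fit.loglik_ratio >= -0.5   # >= 0 up to MC error

    def test_too_few_clusters(self, simple_spec):
        cl = pd.DataFrame({
            "cluster_id": ["c1"], "x_km": [0.0], "y_km": [0.0],
            "n_sampled": [100], "y_bites": [1], "elevation": [0.0],
            "population_density": [0.0], "agri_proportion": [0.0],
            "climate_zone": ["dry"], "stratum": ["s1"],
        })
        with pytest.raises(ValueError, match="20"):
            g.fit_mcml(cl, simple_spec)

    def test_recovery_single_replicate(self, spatial_survey):
        truth, _, clusters = spatial_survey
        fit = g.fit_mcml(clusters, truth.spec,
                         settings=MCSettings(n_burn=800, thin=3, n_keep=400),
                         seed=6)
        se = fit.std_errors[: len(truth.beta)]
        z = np.abs(fit.params.beta - truth.beta) / se
        assert np.all(z < 4)
        total = fit.params.sigma2 + fit.params.tau2
        assert 0.15 < total < 1.2          # truth 0.5; single replicate
        assert fit.diagnostics["n_reanchor"] >= 1


class TestEmpiricalVariogram:
    def test_single_pair(self):
        vg = g.empirical_variogram(np.array([0.0, 2.0]),
                                   np.array([[0.0, 0], [1.0, 0]]),
                                   np.array([0.0, 2.0]))
        assert vg["semivariance"].iloc[0] == pytest.approx(2.0)
        assert vg["n_pairs"].iloc[0] == 1

    def test_constant_residuals(self):
        coords = np.random.default_rng(0).uniform(0, 10, (20, 2))
        vg = g.empirical_variogram(np.full(20, 3.14), coords,
                                   np.array([0.0, 5.0, 10.0]))
        filled = vg["n_pairs"] > 0
        assert np.allclose(vg.loc[filled, "semivariance"], 0.0)

    def test_iid_noise_sill(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(0, 100, (400, 2))
        vals = rng.standard_normal(400)
        vg = g.empirical_variogram(vals, coords,
                                   np.array([0.0, 25.0, 50.0, 75.0]))
        assert np.allclose(vg["semivariance"], 1.0, atol=0.1)

    def test_empty_bin(self):
        vg = g.empirical_variogram(np.array([0.0, 1.0]),
                                   np.array([[0.0, 0], [1.0, 0]]),
                                   np.array([5.0, 6.0]))
        assert vg["n_pairs"].iloc[0] == 0
        assert np.isnan(vg["semivariance"].iloc[0])

    def test_field_plus_nugget_matches_theory(self):
        sigma2, phi, tau2 = 1.0, 5.0, 0.5
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 30, (150, 2))
        edges = np.array([0.0, 2.5, 5.0, 10.0])
        sems = []
        for s in range(40):
            f = g.simulate_field(coords, sigma2, phi, seed=s)
            f = f + np.sqrt(tau2) * np.random.default_rng(900 + s
                                                          ).standard_normal(150)
            sems.append(g.empirical_variogram(f, coords, edges)
                        ["semivariance"])
        mean_vg = np.mean(sems, axis=0)
        d = g.empirical_variogram(np.zeros(150), coords,
                                  edges)["mean_distance"]
        theory = sigma2 * (1 - np.exp(-d / phi)) + tau2
        assert np.all(np.abs(mean_vg - theory) < 0.2)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            g.empirical_variogram(np.array([1.0]), np.array([[0.0, 0]]),
                                  np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            g.empirical_variogram(np.array([1.0, 2.0]),
                                  np.array([[0.0, 0], [1.0, 0]]),
                                  np.array([1.0, 0.5]))
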