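import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import georisk as g
from georisk.geostat import FitResult, LatentFieldSamples, ParamSet
from georisk.mapping import (classify_pcm, exceedance_probability,
                             incidence_surface, krige_conditional,
                             threshold_suite)


def _samples(coords, draws, params):
    return LatentFieldSamples(np.asarray(coords, dtype=float),
                              np.asarray(draws, dtype=float), 0.5, 0, 1,
                              params)


def _fit(params, spec, samples):
    return FitResult(params, np.full(len(params.beta) + 3, np.nan),
                     [], 0.0, spec, samples)


def _intercept_fit(beta0, sigma2=0.3, phi=10.0, tau2=0.0, n_data=20,
                   n_draws=150, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 50, (n_data, 2))
    params = ParamSet(np.array([beta0]), sigma2, phi, tau2)
    cov = sigma2 * np.exp(
        -np.linalg.norm(coords[:, None] - coords[None], axis=2) / phi)
    draws = rng.multivariate_normal(np.zeros(n_data), cov, size=n_draws)
    spec = g.ModelSpec("y_bites", ())
    samples = _samples(coords, draws, params)
    return _fit(params, spec, samples), coords


class TestKrigeConditional:
    def test_interpolates_at_data_locations(self):
        fit, coords = _intercept_fit(-5.0, tau2=0.0)
        target = coords[[2, 7]]
        s = krige_conditional(fit.params, fit.samples, target, seed=1)
        np.testing.assert_allclose(s[:, 0], fit.samples.draws[:, 2],
                                   atol=2e-3)
        np.testing.assert_allclose(s[:, 1], fit.samples.draws[:, 7],
                                   atol=2e-3)

    def test_prior_reversion_far_away(self):
        fit, _ = _intercept_fit(-5.0, sigma2=0.4, phi=5.0, n_draws=2000,
                                seed=3)
        s = krige_conditional(fit.params, fit.samples,
                              np.array([[500.0, 500.0]]), seed=2)
        assert abs(s.mean()) < 4 * np.sqrt(0.4 / 2000) * 3
        assert s.var() == pytest.approx(0.4, rel=0.15)

    def test_closed_form_gaussian_oracle(self):
        # 1-D layout, conditional of S(g) given W at 3 sites, computed
        # by the standard Gaussian conditioning formula by hand
        coords = np.array([[0.0, 0], [10.0, 0], [20.0, 0]])
        sigma2, phi, tau2 = 1.0, 8.0, 0.25
        params = ParamSet(np.array([-5.0]), sigma2, phi, tau2)
        w = np.array([0.5, -0.2, 0.8])
        draws = np.tile(w, (4000, 1))      # degenerate draws: fixed data
        samples = _samples(coords, draws, params)
        gridc = np.array([[5.0, 0.0]])
        s = krige_conditional(params, samples, gridc, seed=5)

        u = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        sig = sigma2 * np.exp(-u / phi) + tau2 * np.eye(3)
        c = sigma2 * np.exp(
            -np.linalg.norm(coords - gridc[0], axis=1) / phi)
        mean_oracle = c @ np.linalg.solve(sig, w)
        var_oracle = sigma2 - c @ np.linalg.solve(sig, c)
        assert s.mean() == pytest.approx(mean_oracle, abs=0.05)
        assert s.var() == pytest.approx(var_oracle, rel=0.15)

    def test_zero_sigma2(self):
        coords = np.array([[0.0, 0], [1.0, 0]])
        params = ParamSet(np.array([-5.0]), 0.0, 1.0, 0.1)
        samples = _samples(coords, np.zeros((50, 2)), params)
        s = krige_conditional(params, samples, np.array([[0.5, 0.0]]))
        assert np.all(s == 0)


class TestIncidenceSurface:
    def _grid(self, m=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "x_km": rng.uniform(0, 50, m), "y_km": rng.uniform(0, 50, m),
            "elevation": rng.uniform(0, 300, m),
            "population_density": rng.uniform(0, 500, m),
            "agri_proportion": rng.uniform(0, 0.3, m),
            "climate_zone": rng.choice(["dry", "wet"], m),
        })

    def test_zero_field_equals_glm_surface(self):
        grid = self._grid()
        spec = g.ModelSpec("y_bites", (g.LinearTerm("elevation"),))
        params = ParamSet(np.array([-6.0, 0.001]), 0.1, 5.0, 0.0)
        samples = _samples(np.zeros((2, 2)), np.zeros((200, 2)), params)
        fit = _fit(params, spec, samples)
        surface, _ = incidence_surface(fit, grid, np.zeros((200, len(grid))))
        expected = 1e5 * np.exp(-6.0 + 0.001 * grid["elevation"])
        np.testing.assert_allclose(surface["estimate"], expected, rtol=1e-10)

    def test_lognormal_correction(self):
        grid = self._grid(m=1)
        spec = g.ModelSpec("y_bites", ())
        params = ParamSet(np.array([-6.0]), 0.1, 5.0, 0.0)
        samples = _samples(np.zeros((2, 2)), np.zeros((5000, 2)), params)
        fit = _fit(params, spec, samples)
        m_, v_ = 0.2, 0.09
        s_draws = (m_ + np.sqrt(v_) * np.random.default_rng(1)
                   .standard_normal((5000, 1)))
        surface, _ = incidence_surface(fit, grid, s_draws)
        oracle = 1e5 * np.exp(-6.0 + m_ + v_ / 2)
        assert surface["estimate"].iloc[0] == pytest.approx(oracle, rel=0.02)

    def test_permutation_invariance(self):
        grid = self._grid(m=20)
        spec = g.ModelSpec("y_bites", (g.LinearTerm("elevation"),))
        params = ParamSet(np.array([-6.0, 0.001]), 0.1, 5.0, 0.0)
        samples = _samples(np.zeros((2, 2)), np.zeros((100, 2)), params)
        fit = _fit(params, spec, samples)
        s_draws = np.random.default_rng(2).normal(0, 0.3, (100, 20))
        perm = np.random.default_rng(3).permutation(20)
        a, _ = incidence_surface(fit, grid, s_draws)
        b, _ = incidence_surface(fit, grid.iloc[perm].reset_index(drop=True),
                                 s_draws[:, perm])
        np.testing.assert_allclose(a["estimate"].to_numpy()[perm],
                                   b["estimate"].to_numpy())


class TestExceedanceProbability:
    def test_all_above(self):
        draws = np.full((200, 3), 1000.0)
        np.testing.assert_array_equal(
            exceedance_probability(draws, 500.0), 1.0)

    def test_symmetric_half(self):
        rng = np.random.default_rng(0)
        draws = 400 + rng.standard_normal((4000, 1)) * 50
        p = exceedance_probability(draws, 400.0)
        assert p[0] == pytest.approx(0.5, abs=0.03)

    def test_gaussian_oracle(self):
        m_, v_ = np.log(398 / 1e5), 0.16
        rng = np.random.default_rng(11)
        draws = 1e5 * np.exp(m_ + np.sqrt(v_)
                             * rng.standard_normal((2000, 1)))
        for t in (300.0, 398.0, 500.0):
            p = exceedance_probability(draws, t)[0]
            oracle = stats.norm.sf((np.log(t / 1e5) - m_) / np.sqrt(v_))
            assert abs(p - oracle) < 0.03

    def test_zero_threshold_certain(self):
        draws = np.random.default_rng(1).uniform(1, 100, (200, 4))
        np.testing.assert_array_equal(exceedance_probability(draws, 0.0), 1.0)

    def test_few_draws_warns(self):
        with pytest.warns(RuntimeWarning, match="draws"):
            exceedance_probability(np.ones((50, 2)), 0.5)


class TestClassifyPCM:
    @pytest.mark.parametrize("p,expected", [
        (0.70, "hot"), (0.30, "cold"), (0.5, "intermediate"),
        (0.71, "hot"), (0.29, "cold"), (1.0, "hot"), (0.0, "cold"),
    ])
    def test_examples(self, p, expected):
        assert classify_pcm(np.array([p]))[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_pcm(np.array([1.2]))
        with pytest.raises(ValueError):
            classify_pcm(np.array([np.nan]))

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=80, deadline=None)
    def test_rule_consistency(self, p):
        c = classify_pcm(np.array([p]))[0]
        if p >= 0.7:
            assert c == "hot"
        elif p <= 0.3:
            assert c == "cold"
        else:
            assert c == "intermediate"


class TestThresholdSuite:
    def _setup(self):
        rng = np.random.default_rng(5)
        m = 40
        grid = pd.DataFrame({
            "x_km": rng.uniform(0, 50, m), "y_km": rng.uniform(0, 50, m),
        })
        spec = g.ModelSpec("y_bites", ())
        params = ParamSet(np.array([np.log(400 / 1e5)]), 0.2, 5.0, 0.0)
        samples = _samples(np.zeros((2, 2)), np.zeros((500, 2)), params)
        fit = _fit(params, spec, samples)
        s_draws = rng.normal(0, 0.4, (500, m)) \
            + np.linspace(-1, 1, m)[None, :]
        return fit, grid, s_draws

    def test_monotone_in_threshold(self):
        fit, grid, s_draws = self._setup()
        maps, summary = threshold_suite(fit, grid, s_draws,
                                        [300.0, 398.0, 500.0])
        assert len(maps) == 3
        hot = summary["hot"].to_numpy()
        assert np.all(np.diff(hot) <= 1e-12)
        for loc in range(len(grid)):
            probs = [m_.probability[loc] for m_ in maps]
            assert np.all(np.diff(probs) <= 1e-12)

    def test_negative_threshold_rejected(self):
        fit, grid, s_draws = self._setup()
        with pytest.raises(ValueError):
            threshold_suite(fit, grid, s_draws, [-10.0])

    def test_rank_consistency_with_estimate(self):
        fit, grid, s_draws = self._setup()
        surface, _ = incidence_surface(fit, grid, s_draws)
        maps, _ = threshold_suite(fit, grid, s_draws, [398.0])
        rho = stats.spearmanr(surface["estimate"],
                              maps[0].probability).statistic
        assert rho > 0.95

    def test_planted_hot_island(self):
        """End-to-end: a planted high-incidence island is classified hot
        at the middle threshold in (nearly) all replicates."""
        from georisk.geostat import MCSettings
        spec = g.ModelSpec("y_bites", ())
        hits = trials = 0
        for rep in range(3):
            rng = np.random.default_rng(100 + rep)
            coords = rng.uniform(0, 60, (80, 2))
            island = (np.linalg.norm(coords - [30, 30], axis=1) < 12)
            eta0 = np.log(300 / 1e5)
            s_true = np.where(island, np.log(1500 / 300), 0.0)
            n = np.full(80, 20_000)
            cl = pd.DataFrame({
                "cluster_id": [f"c{i}" for i in range(80)],
                "x_km": coords[:, 0], "y_km": coords[:, 1],
                "n_sampled": n,
                "y_bites": rng.poisson(n * np.exp(eta0 + s_true)),
                "elevation": 0.0, "population_density": 0.0,
                "agri_proportion": 0.0, "climate_zone": "dry",
                "stratum": "s1",
            })
            fit = g.fit_mcml(cl, spec,
                             settings=MCSettings(n_burn=500, thin=2,
                                                 n_keep=300), seed=rep)
            grid = pd.DataFrame({"x_km": coords[:, 0],
                                 "y_km": coords[:, 1]})
            s_draws = krige_conditional(fit.params, fit.samples,
                                        coords, seed=rep)
            maps, _ = threshold_suite(fit, grid, s_draws, [398.0])
            island_classes = maps[0].classes[island]
            hits += int(np.sum(island_classes == "hot"))
            trials += int(island.sum())
        assert hits / trials >= 0.95
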