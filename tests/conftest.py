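import numpy as np
import pytest

import georisk as g

# reference fixed-effect values used throughout the tests (log-incidence
# scale, bite-model layout: intercept, elevation, elevation hinge at 160,
# zone[intermediate], zone[wet], density, agri, agri hinge at 0.09)
BITE_BETA = np.array([-6.6239, 0.0032, -0.0046, 0.2225, 0.5586,
                      -0.0002, 7.2235, -6.4166])
ENV_BETA = np.array([-6.0911, 0.0043, -0.0046, -0.4781, -0.8093, -0.0005])

SIGMA2, PHI_KM, TAU2 = 0.189, 0.091, 0.304


@pytest.fixture(scope="session")
def small_grid():
    return g.make_domain((90.0, 90.0), 6.0, seed=7)


@pytest.fixture(scope="session")
def simple_spec():
    return g.ModelSpec("y_bites", (g.LinearTerm("elevation"),
                                   g.CategoricalTerm("climate_zone")))


@pytest.fixture(scope="session")
def simple_truth(simple_spec):
    return g.TrueModel(simple_spec, np.array([-5.5, 0.0005, 0.2, 0.5]),
                       sigma2=0.0, phi=1.0, tau2=0.0)


@pytest.fixture(scope="session")
def glm_survey(simple_truth):
    """A survey simulated without any latent variation (pure GLM data)."""
    _, design, clusters = g.simulate_survey(
        simple_truth, extent_km=(90, 90), resolution_km=6, n_strata=9,
        clusters_per_stratum=10, persons_per_cluster_mean=300, seed=21)
    return design, clusters


@pytest.fixture(scope="session")
def spatial_survey(simple_spec):
    """A survey with genuine spatial + nugget variation."""
    truth = g.TrueModel(simple_spec, np.array([-5.5, 0.0005, 0.2, 0.5]),
                        sigma2=0.3, phi=20.0, tau2=0.2)
    _, design, clusters = g.simulate_survey(
        truth, extent_km=(90, 90), resolution_km=6, n_strata=9,
        clusters_per_stratum=20, persons_per_cluster_mean=500, seed=11)
    return truth, design, clusters
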