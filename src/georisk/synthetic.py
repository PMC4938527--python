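"""Synthetic data generation for end-to-end testing of the pipeline.

Generates country-like covariate surfaces on a regular planar grid,
stratified cluster samples, draws of a spatially correlated latent
field with exponential covariance, and Poisson outcome counts.  All
coordinates are planar kilometres and all distances Euclidean.  A
single master seed is split deterministically per stage so stages can
be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.spatial.distance import cdist

from .covariates import CLIMATE_ZONES, ModelSpec, design_matrix

__all__ = [
    "CovariateGrid",
    "TrueModel",
    "make_domain",
    "assign_strata",
    "sample_clusters",
    "simulate_field",
    "simulate_counts",
    "simulate_survey",
    "SurveyDesign",
]

MAX_ELEVATION_M = 2400.0


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage substream of a single master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(8)[stage])


@dataclass
class CovariateGrid:
    """Regular grid of cell centres with covariate surfaces.

    ``cells`` columns: x_km, y_km, elevation (m), population_density
    (persons/km^2), agri_proportion ([0, 1]), climate_zone.
    """

    cells: pd.DataFrame
    extent_km: tuple[float, float]
    resolution_km: float

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["x_km", "y_km"]].to_numpy(dtype=float)

    @property
    def cell_area_km2(self) -> float:
        return self.resolution_km ** 2

    def validate(self) -> None:
        c = self.cells
        numeric = c[["x_km", "y_km", "elevation", "population_density",
                     "agri_proportion"]].to_numpy(dtype=float)
        if not np.isfinite(numeric).all():
            raise ValueError("non-finite covariate values")
        if (c["elevation"] < 0).any() or (c["elevation"] > 2500).any():
            raise ValueError("elevation outside [0, 2500] m")
        if (c["population_density"] < 0).any():
            raise ValueError("negative population density")
        if ((c["agri_proportion"] < 0) | (c["agri_proportion"] > 1)).any():
            raise ValueError("agri_proportion outside [0, 1]")
        if not set(c["climate_zone"]).issubset(CLIMATE_ZONES):
            raise ValueError("unknown climate zone label")


@dataclass
class TrueModel:
    """Generative parameters: fixed effects on the log-incidence scale
    plus spatial variance, correlation range (km) and nugget."""

    spec: ModelSpec
    beta: np.ndarray
    sigma2: float
    phi: float
    tau2: float

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma2 < 0 or self.tau2 < 0:
            raise ValueError("variance components must be >= 0")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")


@dataclass
class SurveyDesign:
    """Strata with population totals; the weighting contract for
    design-based estimation."""

    populations: dict[str, float]

    def __post_init__(self):
        for sid, pop in self.populations.items():
            if pop <= 0:
                raise ValueError(f"stratum {sid!r} has non-positive population")

    @property
    def total_population(self) -> float:
        return float(sum(self.populations.values()))


def _bump_surface(xy: np.ndarray, rng: np.random.Generator,
                  extent: tuple[float, float], n_bumps: int = 8) -> np.ndarray:
    """Smooth surface as a sum of random Gaussian bumps, sd-normalised."""
    ex, ey = extent
    centres = rng.uniform([0, 0], [ex, ey], size=(n_bumps, 2))
    widths = rng.uniform(0.1, 0.35, size=n_bumps) * max(ex, ey)
    heights = rng.uniform(0.3, 1.0, size=n_bumps)
    d2 = cdist(xy, centres, "sqeuclidean")
    surf = (heights * np.exp(-d2 / (2 * widths ** 2))).sum(axis=1)
    return (surf - surf.mean()) / max(surf.std(), 1e-12)


def make_domain(extent_km: tuple[float, float], resolution_km: float,
                seed: int) -> CovariateGrid:
    """Generate covariate surfaces on a regular grid.

    Elevation is a smooth bump surface scaled to [0, 2400] m, population
    density is log-normal around a smooth field, the agricultural-worker
    proportion is anti-correlated with density, and three contiguous
    climate bands (wet / intermediate / dry) run west to east.
    """
    if resolution_km <= 0:
        raise ValueError("resolution_km must be positive")
    ex, ey = float(extent_km[0]), float(extent_km[1])
    if ex <= 0 or ey <= 0:
        raise ValueError("extent must be positive")
    nx, ny = ex / resolution_km, ey / resolution_km
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ValueError("resolution_km must divide both extents")
    nx, ny = int(round(nx)), int(round(ny))

    rng = _stage_rng(seed, 0)
    centres = resolution_km / 2 + resolution_km * np.arange(nx)
    centres_y = resolution_km / 2 + resolution_km * np.arange(ny)
    gx, gy = np.meshgrid(centres, centres_y, indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])

    elev_z = _bump_surface(xy, rng, (ex, ey))
    elev = elev_z - elev_z.min()
    elevation = MAX_ELEVATION_M * elev / max(elev.max(), 1e-12)

    dens_z = _bump_surface(xy, rng, (ex, ey))
    dens_noise = 0.25 * rng.standard_normal(len(xy))
    density = np.exp(5.0 + 0.9 * dens_z + dens_noise)

    agri_noise = 0.8 * rng.standard_normal(len(xy))
    agri = 0.45 / (1.0 + np.exp(-(-1.6 * dens_z - 0.3 + agri_noise)))

    zone = np.where(xy[:, 0] < ex / 3, "wet",
                    np.where(xy[:, 0] < 2 * ex / 3, "intermediate", "dry"))

    cells = pd.DataFrame({
        "x_km": xy[:, 0],
        "y_km": xy[:, 1],
        "elevation": elevation,
        "population_density": density,
        "agri_proportion": agri,
        "climate_zone": zone,
    })
    grid = CovariateGrid(cells, (ex, ey), float(resolution_km))
    grid.validate()
    return grid


def _stratum_shape(n_strata: int) -> tuple[int, int]:
    rows = int(np.sqrt(n_strata))
    while n_strata % rows:
        rows -= 1
    return rows, n_strata // rows


def assign_strata(grid: CovariateGrid, n_strata: int) -> pd.Series:
    """Tile the domain into ``n_strata`` rectangular blocks (near-square
    factorisation) and label each cell with its stratum id."""
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    rows, cols = _stratum_shape(n_strata)
    ex, ey = grid.extent_km
    xy = grid.coords
    ci = np.minimum((xy[:, 0] / (ex / cols)).astype(int), cols - 1)
    ri = np.minimum((xy[:, 1] / (ey / rows)).astype(int), rows - 1)
    return pd.Series([f"s{r * cols + c + 1}" for r, c in zip(ri, ci)],
                     index=grid.cells.index, name="stratum")


def sample_clusters(grid: CovariateGrid, n_strata: int,
                    clusters_per_stratum: int,
                    persons_per_cluster_mean: float = 148.0,
                    seed: int = 0) -> tuple[SurveyDesign, pd.DataFrame]:
    """Draw a stratified cluster sample from the grid.

    Cluster locations are grid cells sampled without replacement within
    each stratum; the sampled population per cluster is Poisson around
    ``persons_per_cluster_mean`` (truncated at 1).  Outcome counts are
    left unset — see :func:`simulate_counts`.
    """
    if persons_per_cluster_mean <= 0:
        raise ValueError("persons_per_cluster_mean must be positive")
    rng = _stage_rng(seed, 1)
    strata = assign_strata(grid, n_strata)
    cells = grid.cells.assign(stratum=strata)

    populations: dict[str, float] = {}
    frames = []
    for sid, block in cells.groupby("stratum", sort=True):
        if clusters_per_stratum > len(block):
            raise ValueError(
                f"requested {clusters_per_stratum} clusters from stratum "
                f"{sid!r} with only {len(block)} cells"
            )
        populations[sid] = float(
            (block["population_density"] * grid.cell_area_km2).sum()
        )
        idx = rng.choice(block.index.to_numpy(), size=clusters_per_stratum,
                         replace=False)
        frames.append(block.loc[np.sort(idx)])
    clusters = pd.concat(frames, ignore_index=True)
    clusters.insert(0, "cluster_id",
                    [f"c{i + 1:04d}" for i in range(len(clusters))])
    n = rng.poisson(persons_per_cluster_mean, size=len(clusters))
    clusters["n_sampled"] = np.maximum(1, n)
    return SurveyDesign(populations), clusters


def simulate_field(coords: np.ndarray, sigma2: float, phi: float,
                   seed: int, jitter: float = 1e-10) -> np.ndarray:
    """One exact zero-mean Gaussian field draw with covariance
    ``sigma2 * exp(-u / phi)`` via Cholesky factorisation.
    """
    coords = np.asarray(coords, dtype=float)
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    rng = _stage_rng(seed, 2)
    m = len(coords)
    if sigma2 == 0:
        return np.zeros(m)
    cov = sigma2 * np.exp(-cdist(coords, coords) / phi)
    for bump in (jitter, 1e-8, 1e-6):
        try:
            L = cholesky(cov + bump * sigma2 * np.eye(m), lower=True)
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError(
            "covariance matrix not positive definite after jitter")
    return L @ rng.standard_normal(m)


def simulate_counts(clusters: pd.DataFrame, true_model: TrueModel,
                    field: np.ndarray, seed: int) -> pd.DataFrame:
    """Attach Poisson counts ``y ~ Poisson(n * exp(beta'd + S + Z))``.

    ``Z`` is iid N(0, tau2) cluster-level noise.  The latent components
    are stored in ``latent_s`` / ``latent_z`` columns for diagnostics.
    """
    rng = _stage_rng(seed, 3)
    n = clusters["n_sampled"].to_numpy(dtype=float)
    if np.any(n <= 0):
        raise ValueError("all sampled populations must be positive")
    field = np.asarray(field, dtype=float)
    if field.shape != (len(clusters),):
        raise ValueError("field length does not match clusters")
    X, _, valid = design_matrix(clusters, true_model.spec)
    if not valid.all():
        raise ValueError("missing covariates in clusters")
    eta = X @ true_model.beta
    z = (np.sqrt(true_model.tau2) * rng.standard_normal(len(clusters))
         if true_model.tau2 > 0 else np.zeros(len(clusters)))
    log_mu = np.log(n) + eta + field + z
    if not np.isfinite(log_mu).all():
        raise ValueError("non-finite linear predictor")
    out = clusters.copy()
    out[true_model.spec.response] = rng.poisson(np.exp(log_mu))
    out["latent_s"] = field
    out["latent_z"] = z
    return out


def simulate_survey(true_model: TrueModel,
                    extent_km: tuple[float, float] = (120.0, 120.0),
                    resolution_km: float = 6.0,
                    n_strata: int = 9,
                    clusters_per_stratum: int = 125,
                    persons_per_cluster_mean: float = 148.0,
                    seed: int = 0
                    ) -> tuple[CovariateGrid, SurveyDesign, pd.DataFrame]:
    """Full generator: domain -> stratified sample -> latent field ->
    counts, all from one master seed."""
    grid = make_domain(extent_km, resolution_km, seed)
    design, clusters = sample_clusters(
        grid, n_strata, clusters_per_stratum, persons_per_cluster_mean, seed)
    coords = clusters[["x_km", "y_km"]].to_numpy(dtype=float)
    field = simulate_field(coords, true_model.sigma2, true_model.phi, seed)
    clusters = simulate_counts(clusters, true_model, field, seed)
    return grid, design, clusters
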