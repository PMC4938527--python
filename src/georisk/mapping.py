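"""Plug-in spatial prediction and exceedance-probability maps.

Given MCML estimates and retained draws of the latent vector at the
data locations, the incidence surface at grid locations is obtained by
conditional simulation: for each retained draw, the spatially
structured component S at the grid is drawn from its exact conditional
Gaussian distribution with the covariance parameters fixed at their
estimates.  The nugget is part of the conditioning model but excluded
from the predictive target, so the mapped quantity is the spatially
continuous incidence exp(beta'd(x) + S(x)).

Exceedance maps report, per location, the fraction of draws whose
incidence exceeds a threshold, classified as hot (p >= 0.7), cold
(p <= 0.3) or intermediate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.spatial.distance import cdist

from .geostat import (FitResult, LatentFieldSamples, ParamSet, cov_matrix,
                      exponential_cov, linear_predictor)

__all__ = [
    "ExceedanceMap",
    "krige_conditional",
    "incidence_surface",
    "exceedance_probability",
    "classify_pcm",
    "threshold_suite",
]

PER = 100_000.0
HOT_PROB = 0.7
COLD_PROB = 0.3
MIN_DRAWS = 100


@dataclass
class ExceedanceMap:
    """Per-location exceedance probabilities for one threshold, with
    the hot / cold / intermediate classification."""

    coords: np.ndarray
    threshold: float              # incidence per 100 000
    probability: np.ndarray
    classes: np.ndarray           # "hot" | "cold" | "intermediate"

    def __post_init__(self):
        p = self.probability
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities outside [0, 1]")

    def area_fractions(self) -> dict[str, float]:
        n = len(self.classes)
        return {c: float(np.mean(self.classes == c))
                for c in ("hot", "intermediate", "cold")} | {"n_locations": n}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_km": self.coords[:, 0],
            "y_km": self.coords[:, 1],
            "probability": self.probability,
            "class": self.classes,
        })


def krige_conditional(params: ParamSet, samples: LatentFieldSamples,
                      grid_coords: np.ndarray, seed: int = 0,
                      jitter: float = 1e-8) -> np.ndarray:
    """Conditional draws of S at ``grid_coords`` given the latent draws.

    For each retained draw W of S + Z at the data locations, S(grid) is
    drawn from the Gaussian conditional N(C Sigma^-1 W, Sigma_gg -
    C Sigma^-1 C') with C = sigma2 R(grid, data), Sigma the full
    data-location covariance including the nugget, and parameters fixed
    at their estimates (plug-in).  Returns an (n_draws, n_grid) array.
    """
    grid_coords = np.asarray(grid_coords, dtype=float)
    data_coords = samples.coords
    draws_w = samples.draws
    rng = np.random.default_rng(seed)
    n_grid = len(grid_coords)
    if params.sigma2 <= 0:
        return np.zeros((len(draws_w), n_grid))

    sigma = cov_matrix(data_coords, params.sigma2, params.phi, params.tau2)
    cf = cho_factor(sigma, lower=True)
    cross = exponential_cov(cdist(grid_coords, data_coords), params.sigma2,
                            params.phi)
    k_weights = cho_solve(cf, cross.T)                    # (n_data, n_grid)
    cond_mean = draws_w @ k_weights                        # (M, n_grid)
    prior_gg = exponential_cov(cdist(grid_coords, grid_coords),
                               params.sigma2, params.phi)
    cond_cov = prior_gg - cross @ k_weights
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    bump = jitter * params.sigma2
    for _ in range(4):
        try:
            l_cond = cholesky(cond_cov + bump * np.eye(n_grid), lower=True)
            break
        except np.linalg.LinAlgError:
            bump *= 100
    else:
        raise np.linalg.LinAlgError("conditional covariance not PSD")
    noise = rng.standard_normal((len(draws_w), n_grid))
    return cond_mean + noise @ l_cond.T


def incidence_surface(fit: FitResult, grid: pd.DataFrame,
                      s_draws: np.ndarray,
                      quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Point-estimate incidence surface (events per 100 000 person-years).

    The point estimate is the conditional mean of exp(beta'd + S) over
    draws — not exp of the mean — so it carries the lognormal
    correction.  Grid locations with missing covariates are masked
    (NaN).  Returns the summary frame and the (n_draws, n_grid) array
    of per-draw incidence values (per 100 000) for exceedance mapping.
    """
    eta = linear_predictor(grid, fit.params.beta, fit.spec)
    valid = np.isfinite(eta)
    inc_draws = np.full((s_draws.shape[0], len(grid)), np.nan)
    inc_draws[:, valid] = PER * np.exp(eta[valid] + s_draws[:, valid])
    out = pd.DataFrame({
        "x_km": grid["x_km"].to_numpy(dtype=float),
        "y_km": grid["y_km"].to_numpy(dtype=float),
        "estimate": np.nanmean(inc_draws, axis=0) if s_draws.size else np.nan,
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for q in quantiles:
            out[f"q{int(round(q * 100)):02d}"] = np.nanquantile(
                inc_draws, q, axis=0)
    out.loc[~valid, out.columns.difference(["x_km", "y_km"])] = np.nan
    return out, inc_draws


def exceedance_probability(inc_draws: np.ndarray,
                           threshold: float) -> np.ndarray:
    """Fraction of draws with incidence above ``threshold`` (per 100 000)."""
    if inc_draws.ndim != 2:
        raise ValueError("expected an (n_draws, n_locations) array")
    if inc_draws.shape[0] < MIN_DRAWS:
        warnings.warn(
            f"only {inc_draws.shape[0]} draws; exceedance probabilities "
            f"are noisy below {MIN_DRAWS}", RuntimeWarning)
    return np.mean(inc_draws > threshold, axis=0)


def classify_pcm(probabilities: np.ndarray, low: float = COLD_PROB,
                 high: float = HOT_PROB) -> np.ndarray:
    """Classify exceedance probabilities: p >= high is "hot", p <= low
    is "cold", otherwise "intermediate" (boundaries inclusive)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    classes = np.full(p.shape, "intermediate", dtype=object)
    classes[p >= high] = "hot"
    classes[p <= low] = "cold"
    return classes


def threshold_suite(fit: FitResult, grid: pd.DataFrame, s_draws: np.ndarray,
                    thresholds: list[float]
                    ) -> tuple[list[ExceedanceMap], pd.DataFrame]:
    """One exceedance map per threshold plus an area-fraction summary."""
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    coords = grid[["x_km", "y_km"]].to_numpy(dtype=float)
    _, inc_draws = incidence_surface(fit, grid, s_draws)
    maps = []
    summary_rows = []
    for t in thresholds:
        prob = exceedance_probability(inc_draws, t)
        prob = np.nan_to_num(prob, nan=0.0)
        pcm = ExceedanceMap(coords, float(t), prob, classify_pcm(prob))
        maps.append(pcm)
        summary_rows.append({"threshold": t} | pcm.area_fractions())
    return maps, pd.DataFrame(summary_rows)
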