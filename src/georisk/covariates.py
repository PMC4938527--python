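"""Non-spatial exploratory modelling of cluster-level counts.

Poisson log-linear GLMs with an offset for the sampled population,
piecewise-linear (hinge) covariate effects, a deviance-profile scan for
breakpoint selection, and Pearson residual diagnostics.  The model
specification objects defined here are shared with the geostatistical
module, which adds a latent spatial field on top of the same linear
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CLIMATE_ZONES",
    "LinearTerm",
    "HingeTerm",
    "CategoricalTerm",
    "ModelSpec",
    "PiecewiseSpec",
    "GLMFit",
    "hinge_basis",
    "design_matrix",
    "fit_glm",
    "select_breakpoint",
    "standardized_residuals",
    "bite_model_spec",
    "envenoming_model_spec",
]

#: Vocabulary of climatic zones; "dry" is the reference category.
CLIMATE_ZONES = ("dry", "intermediate", "wet")


def hinge_basis(x, knot: float):
    """Return the pair ``(x, max(0, x - knot))``.

    The second component is zero below the knot so the coefficient on it
    is the *change* in slope above the knot.  Works elementwise on
    arrays.
    """
    x = np.asarray(x, dtype=float)
    h = np.maximum(0.0, x - knot)
    if x.ndim == 0:
        return float(x), float(h)
    return x, h


@dataclass(frozen=True)
class LinearTerm:
    variable: str

    @property
    def name(self) -> str:
        return self.variable

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        return df[self.variable].to_numpy(dtype=float)[:, None]

    def column_names(self) -> list[str]:
        return [self.variable]


@dataclass(frozen=True)
class HingeTerm:
    variable: str
    knot: float

    @property
    def name(self) -> str:
        return f"hinge({self.variable}, {self.knot:g})"

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        _, h = hinge_basis(df[self.variable].to_numpy(dtype=float), self.knot)
        return h[:, None]

    def column_names(self) -> list[str]:
        return [self.name]


@dataclass(frozen=True)
class CategoricalTerm:
    """Treatment-coded categorical variable with an explicit reference."""

    variable: str
    levels: tuple[str, ...] = CLIMATE_ZONES
    reference: str = "dry"

    @property
    def name(self) -> str:
        return self.variable

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        values = df[self.variable].astype(str).to_numpy()
        unknown = set(values) - set(self.levels)
        if unknown:
            raise ValueError(
                f"unknown levels {sorted(unknown)} for {self.variable!r}; "
                f"expected {self.levels}"
            )
        cols = [
            (values == lev).astype(float)
            for lev in self.levels
            if lev != self.reference
        ]
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    def column_names(self) -> list[str]:
        return [
            f"{self.variable}[{lev}]"
            for lev in self.levels
            if lev != self.reference
        ]


Term = Union[LinearTerm, HingeTerm, CategoricalTerm]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a count model.

    Parameters
    ----------
    response :
        Name of the count column (events per cluster).
    terms :
        Covariate terms; an intercept is always included first.
    offset :
        Name of the exposure column; ``log(offset)`` enters the linear
        predictor with coefficient one, so coefficients are on the
        log-incidence (events per person-year) scale.
    """

    response: str
    terms: tuple[Term, ...]
    offset: str = "n_sampled"

    def with_terms(self, terms: Sequence[Term]) -> "ModelSpec":
        return ModelSpec(self.response, tuple(terms), self.offset)

    @property
    def n_params(self) -> int:
        return 1 + sum(len(t.column_names()) for t in self.terms)


@dataclass(frozen=True)
class PiecewiseSpec:
    """A selected hinge breakpoint with its deviance profile."""

    variable: str
    knot: float
    flat: bool = False
    profile: pd.DataFrame | None = field(default=None, compare=False)


def design_matrix(df: pd.DataFrame, spec: ModelSpec):
    """Build the design matrix for ``spec`` (intercept first).

    Returns ``(X, names, valid)`` where ``valid`` marks rows with all
    covariates present; rows with missing covariates yield NaN columns
    and are flagged rather than silently dropped.
    """
    blocks = [np.ones((len(df), 1))]
    names = ["(Intercept)"]
    for term in spec.terms:
        blocks.append(term.columns(df))
        names.extend(term.column_names())
    X = np.hstack(blocks)
    valid = np.isfinite(X).all(axis=1)
    return X, names, valid


@dataclass
class GLMFit:
    """Result of a Poisson GLM fit (IRLS)."""

    spec: ModelSpec
    params: np.ndarray
    cov_params: np.ndarray
    deviance: float
    llf: float
    fitted: np.ndarray          # mean counts per cluster
    param_names: list[str]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def summary_frame(self) -> pd.DataFrame:
        se = self.bse
        z = np.divide(self.params, se, out=np.full_like(se, np.nan),
                      where=se > 0)
        from scipy import stats
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.params, "std_error": se, "z_value": z,
             "p_value": p},
            index=self.param_names,
        )


def fit_glm(clusters: pd.DataFrame, spec: ModelSpec,
            max_iter: int = 100) -> GLMFit:
    """Fit a Poisson log-link GLM with offset ``log(n)`` by IRLS.

    Raises
    ------
    ValueError
        If the design matrix is rank deficient or IRLS fails to
        converge within ``max_iter`` iterations.
    """
    X, names, valid = design_matrix(clusters, spec)
    if not valid.all():
        raise ValueError(
            f"{int((~valid).sum())} rows have missing covariates; "
            "drop or impute before fitting"
        )
    y = clusters[spec.response].to_numpy(dtype=float)
    n = clusters[spec.offset].to_numpy(dtype=float)
    if np.any(n <= 0):
        raise ValueError("offset column must be strictly positive")
    # a hinge with its knot at (or beyond) the data maximum contributes a
    # zero column: pin its coefficient at 0 instead of failing on rank
    active = ~np.all(X == 0.0, axis=0)
    Xa = X[:, active]
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, Xa, family=sm.families.Poisson(), offset=np.log(n))
    res = model.fit(maxiter=max_iter, tol=1e-10)
    if not res.converged:
        raise ValueError(f"IRLS did not converge in {max_iter} iterations")
    k = X.shape[1]
    params = np.zeros(k)
    params[active] = np.asarray(res.params)
    cov = np.full((k, k), np.nan)
    cov[np.ix_(active, active)] = np.asarray(res.cov_params())
    return GLMFit(
        spec=spec,
        params=params,
        cov_params=cov,
        deviance=float(res.deviance),
        llf=float(res.llf),
        fitted=np.asarray(res.mu),
        param_names=names,
    )


def select_breakpoint(clusters: pd.DataFrame, spec: ModelSpec,
                      variable: str, candidate_knots: Sequence[float],
                      min_improvement: float = 3.84) -> PiecewiseSpec:
    """Scan candidate knots and pick the deviance-minimising hinge.

    For each candidate the model ``spec`` plus a hinge term in
    ``variable`` at that knot is fitted; the candidate with smallest
    deviance wins.  If no candidate improves on the hinge-free model by
    more than ``min_improvement`` deviance units (default: the 5%
    chi-square critical value on 1 df) the profile is declared flat: the
    largest candidate is returned — which reproduces the plain linear
    fit whenever it is at or beyond the data maximum — with
    ``flat=True``.
    """
    candidate_knots = sorted(float(k) for k in candidate_knots)
    if len(candidate_knots) == 0:
        raise ValueError("need at least one candidate knot")
    base_dev = fit_glm(clusters, spec).deviance
    rows = []
    for knot in candidate_knots:
        trial = spec.with_terms(list(spec.terms) + [HingeTerm(variable, knot)])
        try:
            dev = fit_glm(clusters, trial).deviance
        except ValueError:
            dev = np.nan
        rows.append((knot, dev))
    profile = pd.DataFrame(rows, columns=["knot", "deviance"])
    if profile["deviance"].isna().all():
        raise ValueError("no candidate knot produced a fittable model")
    if len(candidate_knots) == 1:
        knot = candidate_knots[0]
        dev = profile["deviance"].iloc[0]
        return PiecewiseSpec(variable, knot,
                             flat=bool(base_dev - dev <= min_improvement),
                             profile=profile)
    best = profile.loc[profile["deviance"].idxmin()]
    if base_dev - best["deviance"] <= min_improvement:
        return PiecewiseSpec(variable, candidate_knots[-1], flat=True,
                             profile=profile)
    return PiecewiseSpec(variable, float(best["knot"]), flat=False,
                         profile=profile)


def standardized_residuals(clusters: pd.DataFrame, fit: GLMFit
                           ) -> pd.DataFrame:
    """Pearson residuals ``(y - mu) / sqrt(mu)`` at cluster locations.

    Residuals are NaN and flagged wherever the fitted mean is zero.
    """
    y = clusters[fit.spec.response].to_numpy(dtype=float)
    mu = np.asarray(fit.fitted, dtype=float)
    undefined = mu <= 0
    resid = np.full_like(mu, np.nan)
    ok = ~undefined
    resid[ok] = (y[ok] - mu[ok]) / np.sqrt(mu[ok])
    out = pd.DataFrame({
        "cluster_id": clusters.get("cluster_id", pd.RangeIndex(len(clusters))),
        "residual": resid,
        "undefined": undefined,
    })
    for col in ("x_km", "y_km"):
        if col in clusters.columns:
            out[col] = clusters[col].to_numpy()
    return out


def bite_model_spec(elevation_knot: float = 160.0,
                    agri_knot: float = 0.09) -> ModelSpec:
    """Standard bite-incidence model: elevation and agricultural-worker
    share enter piecewise-linearly, plus climate zone and density.

    The agricultural-worker share is a proportion in [0, 1]; the default
    knot 0.09 corresponds to 9%.
    """
    return ModelSpec(
        response="y_bites",
        terms=(
            LinearTerm("elevation"),
            HingeTerm("elevation", elevation_knot),
            CategoricalTerm("climate_zone"),
            LinearTerm("population_density"),
            LinearTerm("agri_proportion"),
            HingeTerm("agri_proportion", agri_knot),
        ),
    )


def envenoming_model_spec(elevation_knot: float = 195.0) -> ModelSpec:
    """Envenoming model: spatial variables only (no occupation term)."""
    return ModelSpec(
        response="y_envenoming",
        terms=(
            LinearTerm("elevation"),
            HingeTerm("elevation", elevation_knot),
            CategoricalTerm("climate_zone"),
            LinearTerm("population_density"),
        ),
    )
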