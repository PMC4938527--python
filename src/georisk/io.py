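"""File formats and validated readers/writers.

Cluster tables are comma-separated UTF-8 CSV with a header.  The
coordinate columns declare the reference system: ``x_km``/``y_km`` for
pre-projected planar kilometres, or ``lon``/``lat`` in decimal degrees,
which are projected internally with an equirectangular projection at
the domain mid-latitude so that all distances are metric.  A column
mapping can rename arbitrary input headers onto the documented schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import CLIMATE_ZONES
from .synthetic import CovariateGrid, SurveyDesign

__all__ = [
    "ClusterRecord",
    "read_clusters",
    "write_clusters",
    "read_grid",
    "write_grid",
    "read_strata",
    "write_strata",
    "project_lonlat",
]

EARTH_RADIUS_KM = 6371.0

_REQUIRED = ["cluster_id", "n_sampled", "elevation", "population_density",
             "agri_proportion", "climate_zone", "stratum"]
_COUNTS = ["y_bites", "y_envenoming"]
_NUMERIC = ["n_sampled", "elevation", "population_density",
            "agri_proportion", "x_km", "y_km", "lon", "lat",
            "y_bites", "y_envenoming"]


@dataclass(frozen=True)
class ClusterRecord:
    """One sampled cluster (validated row of the cluster table)."""

    cluster_id: str
    x_km: float
    y_km: float
    n_sampled: int
    elevation: float
    population_density: float
    agri_proportion: float
    climate_zone: str
    stratum: str
    y_bites: int | None = None
    y_envenoming: int | None = None

    def validate(self) -> None:
        if self.n_sampled <= 0:
            raise ValueError("n_sampled must be > 0")
        if self.climate_zone not in CLIMATE_ZONES:
            raise ValueError(f"climate_zone {self.climate_zone!r} not in "
                             f"{CLIMATE_ZONES}")
        if not 0 <= self.agri_proportion <= 1:
            raise ValueError("agri_proportion outside [0, 1]")
        if self.population_density < 0:
            raise ValueError("population_density must be >= 0")
        if self.y_bites is not None and self.y_bites < 0:
            raise ValueError("y_bites must be >= 0")
        if self.y_envenoming is not None:
            if self.y_envenoming < 0:
                raise ValueError("y_envenoming must be >= 0")
            if self.y_bites is not None and self.y_envenoming > self.y_bites:
                raise ValueError("y_envenoming exceeds y_bites")


def project_lonlat(lon: np.ndarray, lat: np.ndarray,
                   lat0: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection of lon/lat degrees to planar km at the
    mid-latitude ``lat0`` (default: mean latitude of the data)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lat0 is None:
        lat0 = float(lat.mean())
    x = np.radians(lon - lon.min()) * EARTH_RADIUS_KM * np.cos(
        np.radians(lat0))
    y = np.radians(lat - lat.min()) * EARTH_RADIUS_KM
    return x, y


def _fail(path, row, field, message):
    raise ValueError(f"{path}: row {row}, field {field!r}: {message}")


def read_clusters(path, column_map: dict[str, str] | None = None
                  ) -> pd.DataFrame:
    """Read and validate a cluster table.

    ``column_map`` maps input header names onto schema names.  Errors
    name the offending (1-based, header-exclusive) row and field.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records (empty file)") from None
    if column_map:
        df = df.rename(columns=column_map)
    if len(df) == 0:
        raise ValueError(f"{path}: no records")

    missing = [c for c in _REQUIRED if c not in df.columns]
    has_xy = {"x_km", "y_km"}.issubset(df.columns)
    has_ll = {"lon", "lat"}.issubset(df.columns)
    if not (has_xy or has_ll):
        missing.append("x_km/y_km or lon/lat")
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    for col in _NUMERIC:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            _fail(path, row, col, f"unparsable value {df[col][bad.idxmax()]!r}")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 1
            _fail(path, row, col, "missing value")
        df[col] = parsed

    if not has_xy:
        x, y = project_lonlat(df["lon"].to_numpy(), df["lat"].to_numpy())
        df["x_km"], df["y_km"] = x, y

    for i, row in df.iterrows():
        rec = ClusterRecord(
            cluster_id=str(row["cluster_id"]),
            x_km=float(row["x_km"]), y_km=float(row["y_km"]),
            n_sampled=int(row["n_sampled"]),
            elevation=float(row["elevation"]),
            population_density=float(row["population_density"]),
            agri_proportion=float(row["agri_proportion"]),
            climate_zone=str(row["climate_zone"]),
            stratum=str(row["stratum"]),
            y_bites=int(row["y_bites"]) if "y_bites" in df.columns else None,
            y_envenoming=(int(row["y_envenoming"])
                          if "y_envenoming" in df.columns else None),
        )
        try:
            rec.validate()
        except ValueError as exc:
            _fail(path, int(i) + 1, "record", str(exc))
    for col in ("n_sampled", "y_bites", "y_envenoming"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df


def write_clusters(df: pd.DataFrame, path) -> None:
    cols = ["cluster_id", "stratum", "x_km", "y_km", "n_sampled",
            "elevation", "population_density", "agri_proportion",
            "climate_zone"] + [c for c in _COUNTS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_grid(path) -> pd.DataFrame:
    """Read a prediction-grid CSV (x_km, y_km + covariates)."""
    df = pd.read_csv(path, encoding="utf-8")
    needed = ["x_km", "y_km", "elevation", "population_density",
              "agri_proportion", "climate_zone"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing grid columns {missing}")
    return df


def write_grid(grid: CovariateGrid | pd.DataFrame, path) -> None:
    df = grid.cells if isinstance(grid, CovariateGrid) else grid
    df.to_csv(path, index=False)


def read_strata(path) -> SurveyDesign:
    """Read a strata CSV (columns: stratum, population)."""
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("stratum", "population"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return SurveyDesign({str(r.stratum): float(r.population)
                         for r in df.itertuples()})


def write_strata(design: SurveyDesign, path) -> None:
    pd.DataFrame(
        {"stratum": list(design.populations),
         "population": list(design.populations.values())}
    ).to_csv(path, index=False)
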