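"""Design-based incidence estimation for stratified two-stage cluster
samples.

Rates are ratio estimates (events over person-years) with Taylor
linearization variances treating first-stage clusters as sampled with
replacement — no finite-population correction, matching sampling
fractions of the order of 1%.  Confidence intervals are normal-based
and truncated at zero.  National figures combine stratum estimates with
population weights; totals are extrapolated by scaling rates to the
stratum population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SurveyDesign

__all__ = [
    "RateEstimate",
    "stratum_rate",
    "national_rate",
    "extrapolate_count",
    "survey_table",
    "SurveyDesign",
]

PER = 100_000.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RateEstimate:
    """An incidence rate per 100 000 person-years with its design-based
    confidence interval.

    ``variance`` is on the per-100 000 scale.  ``ci_available`` is False
    when the design provides no variance estimate (single cluster).
    """

    rate: float
    ci_low: float
    ci_high: float
    variance: float
    n_events: int
    n_persons: int
    ci_available: bool = True
    estimated_count: int | None = None
    count_ci: tuple[int, int] | None = None

    def __post_init__(self):
        if self.ci_available and not (
                self.ci_low - 1e-9 <= self.rate <= self.ci_high + 1e-9):
            raise ValueError("CI does not bracket the rate")


def stratum_rate(y: np.ndarray, n: np.ndarray,
                 level: float = 0.95) -> RateEstimate:
    """Ratio estimate of the incidence rate within one stratum.

    rate = 100000 * sum(y) / sum(n); the variance is the linearized
    ratio variance with clusters treated as with-replacement PSUs:

        V(R) = m / (m - 1) * sum((y_i - R n_i)^2) / (sum n)^2

    With a single cluster the rate is returned with the CI flagged
    unavailable.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if y.shape != n.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("y and n must be equal-length 1-d arrays")
    if np.any(n <= 0):
        raise ValueError("all cluster populations must be positive")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    m = len(y)
    total_n = n.sum()
    ratio = y.sum() / total_n
    rate = PER * ratio
    if m < 2:
        return RateEstimate(rate, np.nan, np.nan, np.nan,
                            int(y.sum()), int(total_n), ci_available=False)
    z_resid = y - ratio * n
    var_ratio = m / (m - 1) * np.sum(z_resid ** 2) / total_n ** 2
    variance = PER ** 2 * var_ratio
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * math.sqrt(variance)
    return RateEstimate(rate, max(0.0, rate - half), rate + half, variance,
                        int(y.sum()), int(total_n))


def national_rate(stratum_estimates: dict[str, RateEstimate],
                  design: SurveyDesign, level: float = 0.95) -> RateEstimate:
    """Population-weighted combination of stratum rates.

    Weights are stratum population shares; the variance is the weighted
    sum of the independent stratum variances.
    """
    missing = set(design.populations) - set(stratum_estimates)
    if missing:
        raise ValueError(f"missing estimates for strata {sorted(missing)}")
    total_pop = design.total_population
    rate = 0.0
    variance = 0.0
    n_events = 0
    n_persons = 0
    for sid, pop in design.populations.items():
        est = stratum_estimates[sid]
        w = pop / total_pop
        rate += w * est.rate
        if est.ci_available:
            variance += w ** 2 * est.variance
        n_events += est.n_events
        n_persons += est.n_persons
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * math.sqrt(variance)
    return RateEstimate(rate, max(0.0, rate - half), rate + half, variance,
                        n_events, n_persons)


def extrapolate_count(estimate: RateEstimate, population: float
                      ) -> RateEstimate:
    """Scale a rate to an event count for a population of given size.

    count = rate / 100000 * population, rounded half-up; CI endpoints
    are scaled identically.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    count = _round_half_up(estimate.rate / PER * population)
    if estimate.ci_available:
        ci = (_round_half_up(estimate.ci_low / PER * population),
              _round_half_up(estimate.ci_high / PER * population))
    else:
        ci = None
    return replace(estimate, estimated_count=count, count_ci=ci)


def survey_table(clusters: pd.DataFrame, design: SurveyDesign,
                 response: str = "y_bites", offset: str = "n_sampled",
                 stratum_col: str = "stratum") -> pd.DataFrame:
    """Per-stratum and national incidence table (one row per stratum
    plus a ``total`` row), with extrapolated event counts.
    """
    seen = set(clusters[stratum_col].unique())
    if seen != set(design.populations):
        raise ValueError("cluster strata do not match the survey design")
    per_stratum: dict[str, RateEstimate] = {}
    rows = []
    for sid in design.populations:
        block = clusters[clusters[stratum_col] == sid]
        est = stratum_rate(block[response].to_numpy(),
                           block[offset].to_numpy())
        est = extrapolate_count(est, design.populations[sid])
        per_stratum[sid] = est
        rows.append(_row(sid, est, len(block)))
    nat = national_rate(per_stratum, design)
    nat = extrapolate_count(nat, design.total_population)
    rows.append(_row("total", nat, len(clusters)))
    return pd.DataFrame(rows)


def _row(sid: str, est: RateEstimate, n_clusters: int) -> dict:
    return {
        "stratum": sid,
        "n_clusters": n_clusters,
        "reported": est.n_events,
        "sampled_population": est.n_persons,
        "estimated_count": est.estimated_count,
        "rate_per_100k": est.rate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
    }
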