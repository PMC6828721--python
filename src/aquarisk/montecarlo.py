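"""Seeded Monte Carlo propagation of concentration and exposure uncertainty.

A simulation draws n joint realizations of the concentration and of any
exposure factor declared as a distribution, pushes them through the dose and
risk equations, and summarizes the resulting risk sample by mean/SD, upper
percentiles (surveys of this kind report the 90th, 95th, 99th and 99.9th) and the
fraction exceeding a regulatory threshold.  The closed-form normal exceedance
1 − Φ((t − µ)/σ) is provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distributions import DistributionSpec
from .errors import DomainError, RouteError
from .exposure import (
    CARCINOGENIC_LIFETIME_YEARS,
    DERMAL,
    INGESTION,
    ExposureProfile,
    ToxicityReference,
    cdi_dermal,
    cdi_ingestion,
    hazard_quotient,
    lifetime_cancer_risk,
    _STOCHASTIC_FIELDS,
)

__all__ = [
    "DEFAULT_ITERATIONS",
    "REPORTED_PERCENTILES",
    "RiskDistribution",
    "PercentileSummary",
    "simulate_risk",
    "percentile_summary",
    "exceedance_fraction",
    "analytic_exceedance_normal",
]

DEFAULT_ITERATIONS = 10_000
REPORTED_PERCENTILES = (5.0, 50.0, 90.0, 95.0, 99.0, 99.9)


@dataclass
class RiskDistribution:
    """Monte Carlo risk sample for one (metal, stratum, population, route) cell."""

    draws: np.ndarray
    metal: str | None = None
    district: str | None = None
    source_type: str | None = None
    population: str | None = None
    route: str = INGESTION
    endpoint: str = "HQ"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.size < 1:
            raise DomainError("a risk distribution needs at least one draw")
        if not np.all(np.isfinite(self.draws)) or np.any(self.draws < 0):
            raise DomainError("risk draws must be finite and non-negative")

    @property
    def n(self) -> int:
        return int(self.draws.size)

    def summary(self, levels=REPORTED_PERCENTILES) -> "PercentileSummary":
        return percentile_summary(self, levels)

    def exceedance(self, threshold: float) -> float:
        return exceedance_fraction(self, threshold)


@dataclass(frozen=True)
class PercentileSummary:
    """Mean, SD and selected percentiles of a risk sample."""

    mean: float
    sd: float
    percentiles: dict[float, float]

    def __getitem__(self, level: float) -> float:
        return self.percentiles[level]


def _draws_of(dist_or_draws) -> np.ndarray:
    if isinstance(dist_or_draws, RiskDistribution):
        return dist_or_draws.draws
    return np.asarray(dist_or_draws, dtype=float)


def simulate_risk(
    conc_dist: DistributionSpec,
    profile: ExposureProfile,
    tox: ToxicityReference,
    metal: str,
    route: str = INGESTION,
    endpoint: str = "HQ",
    n: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    district: str | None = None,
    source_type: str | None = None,
) -> RiskDistribution:
    """Propagate joint input draws through the risk equations.

    Exposure factors that are :class:`DistributionSpec`s are sampled from
    independent substreams of ``seed`` (one per factor, in a fixed order), so
    adding a distribution to one factor does not perturb the draws of
    another.  Negative tails of unbounded factor distributions are clipped at
    zero.  If ``profile.at_r`` is unset the endpoint convention applies:
    AT = ED × 365 for HQ, 70 × 365 for LTCR.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if endpoint not in ("HQ", "LTCR"):
        raise DomainError(f"unknown endpoint {endpoint!r}")
    if endpoint == "LTCR" and route == DERMAL:
        raise RouteError("cancer risk is computed for the ingestion route only")

    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(child)
               for child in ss.spawn(1 + len(_STOCHASTIC_FIELDS))]
    c = conc_dist.sample(n, streams[0])

    resolved = {}
    for stream, fname in zip(streams[1:], _STOCHASTIC_FIELDS):
        v = getattr(profile, fname)
        if isinstance(v, DistributionSpec):
            resolved[fname] = np.clip(v.sample(n, stream), 0.0, None)
    point_profile = profile if not resolved else _with_arrays(profile, resolved)

    if profile.at_r is not None:
        at = profile.at_r
    elif endpoint == "HQ":
        ed = resolved.get("ed", getattr(profile, "ed"))
        at = np.asarray(ed, dtype=float) * 365.0
    else:
        at = CARCINOGENIC_LIFETIME_YEARS * 365.0

    if route == INGESTION:
        dose = cdi_ingestion(c, point_profile, metal=metal, at_r=at)
    elif route == DERMAL:
        dose = cdi_dermal(c, point_profile, metal=metal, at_r=at)
    else:
        raise RouteError(f"unknown route {route!r}")

    if endpoint == "HQ":
        draws = hazard_quotient(dose, tox)
    else:
        draws, _ = lifetime_cancer_risk(dose, tox)

    return RiskDistribution(
        np.asarray(draws, dtype=float), metal=metal, district=district,
        source_type=source_type, population=profile.name, route=route,
        endpoint=endpoint, seed=seed,
    )


def _with_arrays(profile: ExposureProfile, resolved: dict) -> ExposureProfile:
    from dataclasses import replace

    return replace(profile, **resolved)


def percentile_summary(dist, levels=REPORTED_PERCENTILES) -> PercentileSummary:
    """Empirical mean/SD and linear-interpolation percentiles.

    Quantiles use the sorted-sample linear interpolation convention
    (Hyndman–Fan type 7, the spreadsheet default).
    """
    draws = _draws_of(dist)
    levels = tuple(float(l) for l in levels)
    for l in levels:
        if not 0 < l < 100:
            raise DomainError(f"percentile level {l} outside (0, 100)")
    qs = np.percentile(draws, levels, method="linear")
    sd = float(draws.std(ddof=1)) if draws.size > 1 else 0.0
    return PercentileSummary(
        mean=float(draws.mean()), sd=sd,
        percentiles={l: float(q) for l, q in zip(levels, qs)},
    )


def exceedance_fraction(dist, threshold: float) -> float:
    """Percent of draws strictly above ``threshold``."""
    draws = _draws_of(dist)
    return 100.0 * float(np.count_nonzero(draws > threshold)) / draws.size


def analytic_exceedance_normal(mean: float, sd: float, threshold: float) -> float:
    """P(X > t) for X ~ Normal(mean, sd): the closed-form simulation oracle."""
    if not sd > 0:
        raise DomainError("sd must be positive")
    return float(stats.norm.sf((threshold - mean) / sd))
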