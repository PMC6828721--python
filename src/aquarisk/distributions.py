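"""Parametric random-variable specifications and moment-inversion fits.

A :class:`DistributionSpec` is a small, serializable description of a random
variable — family, parameters, optional truncation bounds — used both for
concentrations (fitted to printed summary statistics) and for exposure
factors.  Sampling is done by inverse-CDF transform of uniform variates from
a :class:`numpy.random.Generator`, which makes truncation exact and keeps a
fixed seed byte-reproducible.

The moment-inversion helpers invert the two summary forms this kind of study
prints: a (mean, sd) pair, and a (5th, 95th) percentile pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, special, stats

from .errors import DomainError, FeasibilityError

__all__ = [
    "DistributionSpec",
    "fit_lognormal_from_summary",
    "fit_normal_from_percentiles",
    "fit_lognormal_from_percentiles",
    "fit_truncated_lognormal",
]

_FAMILIES = ("point", "normal", "lognormal", "uniform", "triangular")


@dataclass(frozen=True)
class DistributionSpec:
    """Family + parameters (+ optional truncation) for one random variable.

    Parameter conventions per family:

    - ``point``:      (value,)
    - ``normal``:     (mean, sd)
    - ``lognormal``:  (mu, sigma) of the underlying normal on the log scale
    - ``uniform``:    (lower, upper)
    - ``triangular``: (lower, mode, upper)
    """

    family: str
    params: tuple[float, ...]
    truncation: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise DomainError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.family == "point" and len(p) != 1:
            raise DomainError("point family takes a single value")
        if self.family == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise DomainError("normal family takes (mean, sd) with sd > 0")
        if self.family == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise DomainError("lognormal family takes (mu, sigma) with sigma > 0")
        if self.family == "uniform":
            if len(p) != 2 or not p[0] < p[1]:
                raise DomainError("uniform family takes (lower, upper), ordered")
        if self.family == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]) or p[0] == p[2]:
                raise DomainError("triangular family takes (lower, mode, upper)")
        if self.truncation is not None:
            lo, hi = self.truncation
            object.__setattr__(self, "truncation", (float(lo), float(hi)))
            if not lo < hi:
                raise DomainError("truncation bounds must be ordered")
            if self.family != "point":
                d = self._frozen()
                if not d.cdf(hi) - d.cdf(lo) > 0:
                    raise DomainError("truncation interval carries no probability mass")

    # -- scipy plumbing ---------------------------------------------------

    def _frozen(self):
        p = self.params
        if self.family == "normal":
            return stats.norm(loc=p[0], scale=p[1])
        if self.family == "lognormal":
            return stats.lognorm(s=p[1], scale=math.exp(p[0]))
        if self.family == "uniform":
            return stats.uniform(loc=p[0], scale=p[1] - p[0])
        if self.family == "triangular":
            lo, mode, hi = p
            return stats.triang(c=(mode - lo) / (hi - lo), loc=lo, scale=hi - lo)
        raise DomainError(f"no continuous form for family {self.family!r}")

    # -- sampling and quantiles -------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values by inverse-CDF transform; truncation is exact."""
        if n < 0:
            raise DomainError("n must be non-negative")
        if self.family == "point":
            return np.full(n, self.params[0])
        return np.asarray(self.ppf(rng.random(n)), dtype=float)

    def ppf(self, q):
        """Quantile function, truncation-aware.

        Truncated normal/lognormal quantiles go through
        :class:`scipy.stats.truncnorm`, which stays accurate when the window
        sits deep in a tail; results are clipped to the window as a
        floating-point guard.
        """
        if self.family == "point":
            return np.broadcast_to(self.params[0], np.shape(q)).astype(float) \
                if np.ndim(q) else self.params[0]
        d = self._frozen()
        if self.truncation is None:
            return d.ppf(q)
        lo, hi = self.truncation
        if self.family in ("normal", "lognormal"):
            m, s = self.params
            if self.family == "normal":
                a, b = (lo - m) / s, (hi - m) / s
                out = stats.truncnorm.ppf(q, a, b, loc=m, scale=s)
            else:
                log_lo = math.log(lo) if lo > 0 else -math.inf
                a, b = (log_lo - m) / s, (math.log(hi) - m) / s
                out = np.exp(m + s * stats.truncnorm.ppf(q, a, b))
        else:
            c_lo, c_hi = d.cdf(lo), d.cdf(hi)
            out = d.ppf(c_lo + np.asarray(q) * (c_hi - c_lo))
        return np.clip(out, lo, hi)

    def mean(self) -> float:
        """Analytic mean (closed-form for truncated normal/lognormal)."""
        p = self.params
        if self.family == "point":
            return p[0]
        if self.truncation is None:
            return float(self._frozen().mean())
        lo, hi = self.truncation
        if self.family == "normal":
            a, b = (lo - p[0]) / p[1], (hi - p[0]) / p[1]
            return float(stats.truncnorm(a, b, loc=p[0], scale=p[1]).mean())
        if self.family == "lognormal":
            return _truncated_lognormal_mean(p[0], p[1], lo, hi)
        raise NotImplementedError(
            f"truncated mean not implemented for family {self.family!r}"
        )

    def sd(self) -> float:
        if self.family == "point":
            return 0.0
        if self.truncation is None:
            return float(self._frozen().std())
        lo, hi = self.truncation
        if self.family == "normal":
            p = self.params
            a, b = (lo - p[0]) / p[1], (hi - p[0]) / p[1]
            return float(stats.truncnorm(a, b, loc=p[0], scale=p[1]).std())
        raise NotImplementedError(
            f"truncated sd not implemented for family {self.family!r}"
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {"family": self.family, "params": list(self.params)}
        if self.truncation is not None:
            d["truncation"] = list(self.truncation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        trunc = d.get("truncation")
        return cls(d["family"], tuple(d["params"]),
                   tuple(trunc) if trunc is not None else None)


def _truncated_lognormal_moments(
    mu: float, sigma: float, lo: float, hi: float
) -> tuple[float, float]:
    """(mean, sd) of X ~ LogNormal(mu, sigma) conditioned on lo < X < hi."""
    lo = max(lo, 0.0)
    alpha = (math.log(lo) - mu) / sigma if lo > 0 else -math.inf
    beta = (math.log(hi) - mu) / sigma if math.isfinite(hi) else math.inf
    mass = _phi_diff(alpha, beta)
    if mass <= 1e-300:
        # nearly all mass lies outside the window; the conditional law
        # collapses onto the nearer bound (needed while bracketing a solve)
        if not math.isfinite(beta):
            edge = lo if lo > 0 else hi
        else:
            edge = hi if beta <= 0 else lo
        return edge, 0.0
    m1 = math.exp(mu + 0.5 * sigma**2) * _phi_diff(alpha - sigma,
                                                   beta - sigma) / mass
    m2 = math.exp(2 * mu + 2 * sigma**2) * _phi_diff(alpha - 2 * sigma,
                                                     beta - 2 * sigma) / mass
    return float(m1), float(math.sqrt(max(m2 - m1**2, 0.0)))


def _phi_diff(a: float, b: float) -> float:
    """Phi(b) - Phi(a) without cancellation when both sit in one tail."""
    if a >= 0:  # upper tail: use survival functions
        return float(special.ndtr(-a) - special.ndtr(-b))
    return float(special.ndtr(b) - special.ndtr(a))


def _truncated_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    return _truncated_lognormal_moments(mu, sigma, lo, hi)[0]


def fit_lognormal_from_summary(mean: float, sd: float) -> DistributionSpec:
    """Lognormal whose analytic mean/sd equal the inputs (moment inversion).

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2 / 2.  A zero sd is
    accepted as the degenerate limit and returns a point mass.
    """
    if not (mean > 0) or sd < 0:
        raise DomainError("fit_lognormal_from_summary requires mean > 0 and sd >= 0")
    if sd == 0:
        return DistributionSpec("point", (mean,))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return DistributionSpec("lognormal", (mu, math.sqrt(sigma2)))


def fit_normal_from_percentiles(
    p_low: float, p_high: float, levels: tuple[float, float] = (0.05, 0.95)
) -> DistributionSpec:
    """Normal through two quantiles.

    For symmetric levels (l, 1-l) this is mean = midpoint and
    sd = (p_high - p_low) / (2 z_{1-l}); the general two-quantile solve is
    used so asymmetric level pairs also work.
    """
    if not p_low < p_high:
        raise DomainError("percentile inputs must be ordered p_low < p_high")
    l1, l2 = levels
    if not (0 < l1 < l2 < 1):
        raise DomainError("levels must be ordered probabilities in (0, 1)")
    z1, z2 = stats.norm.ppf(l1), stats.norm.ppf(l2)
    sd = (p_high - p_low) / (z2 - z1)
    mean = p_low - z1 * sd
    return DistributionSpec("normal", (mean, sd))


def fit_lognormal_from_percentiles(
    p_low: float, p_high: float, levels: tuple[float, float] = (0.05, 0.95)
) -> DistributionSpec:
    """Lognormal through two quantiles (normal fit on the log scale)."""
    if not (0 < p_low < p_high):
        raise DomainError("percentile inputs must be positive and ordered")
    spec = fit_normal_from_percentiles(math.log(p_low), math.log(p_high), levels)
    return DistributionSpec("lognormal", spec.params)


def _solve_mean_matching_mu(
    mean: float, sigma: float, lower: float, upper: float
) -> float:
    """mu such that the [lower, upper]-truncated lognormal mean equals ``mean``."""

    def gap(mu: float) -> float:
        return _truncated_lognormal_mean(mu, sigma, lower, upper) - mean

    mu0 = math.log(mean)
    step = max(1.0, sigma)
    lo_mu, hi_mu = mu0 - step, mu0 + step
    for _ in range(60):
        if gap(lo_mu) < 0:
            break
        step *= 2.0
        lo_mu -= step
    step = max(1.0, sigma)
    for _ in range(60):
        if gap(hi_mu) > 0:
            break
        step *= 2.0
        hi_mu += step
    if not (gap(lo_mu) < 0 < gap(hi_mu)):
        raise FeasibilityError("could not bracket a mean-matching solution")
    return optimize.brentq(gap, lo_mu, hi_mu, xtol=1e-13)


@lru_cache(maxsize=512)
def fit_truncated_lognormal(
    mean: float, sd: float, lower: float, upper: float
) -> DistributionSpec:
    """Truncated lognormal on [lower, upper] matching the *truncated* moments.

    Both truncated moments are solved for (mu, sigma) where the window
    supports them; when the target sd is unreachable inside the window (a
    narrow printed range cannot carry a heavy spread) sigma falls back to the
    untruncated moment fit and only the truncated mean is matched — the mean
    is the quantity downstream stages recover, so it is never sacrificed.
    """
    if not (mean > 0 and sd >= 0):
        raise DomainError("mean must be positive, sd non-negative")
    if not (lower < mean < upper):
        raise FeasibilityError(
            f"target mean {mean} lies outside the bounds [{lower}, {upper}]"
        )
    if sd == 0:
        return DistributionSpec("point", (mean,))
    base = fit_lognormal_from_summary(mean, sd)
    mu0, sigma0 = base.params
    d = base._frozen()
    if d.cdf(upper) - d.cdf(max(lower, 0.0)) > 1 - 1e-9:
        return DistributionSpec("lognormal", (mu0, sigma0), truncation=(lower, upper))

    # nested solve: the inner brentq pins the truncated mean for any sigma,
    # the outer brentq then matches the truncated sd (monotone in sigma)
    def sd_gap(sigma: float) -> float:
        mu = _solve_mean_matching_mu(mean, sigma, lower, upper)
        return _truncated_lognormal_moments(mu, sigma, lower, upper)[1] - sd

    sig_lo, sig_hi = 1e-6, 5.0
    try:
        if sd_gap(sig_lo) < 0 < sd_gap(sig_hi):
            sigma = optimize.brentq(sd_gap, sig_lo, sig_hi, xtol=1e-12)
            mu = _solve_mean_matching_mu(mean, sigma, lower, upper)
            return DistributionSpec("lognormal", (mu, sigma),
                                    truncation=(lower, upper))
    except (ValueError, FloatingPointError, OverflowError):
        pass
    # the window cannot carry the target spread: fix sigma at the untruncated
    # shape and match the mean only — the mean is what downstream recovers
    mu = _solve_mean_matching_mu(mean, sigma0, lower, upper)
    return DistributionSpec("lognormal", (mu, sigma0), truncation=(lower, upper))
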