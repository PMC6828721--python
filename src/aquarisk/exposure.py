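"""Deterministic dose and risk equations with toxicity-reference tables.

The chronic daily intake (CDI, µg/kg·day) of a metal in drinking water is

    CDI_ingestion = C · IR_w · EF_r · ED / (BW · AT_r)
    CDI_dermal    = C · SA · K_p · EF_r · ED · ET · CF / (BW · AT_r)

with C the concentration (µg/L), IR_w the intake rate (L/day), EF_r the
exposure frequency (days/year), ED the exposure duration (years), BW body
weight (kg), AT_r the averaging time (days), SA exposed skin (cm²), K_p the
dermal permeability coefficient (cm/h), ET exposure time (h/day) and CF the
volume conversion 0.001 L/cm³.  The hazard quotient divides the CDI by the
route-specific reference dose; the lifetime cancer risk multiplies the
ingestion CDI (in mg/kg·day) by the oral slope factor.

Averaging-time conventions: non-carcinogenic AT_r = ED × 365 days (so the
ingestion CDI is algebraically independent of ED), carcinogenic
AT_r = 70 × 365 days.

All arithmetic operates element-wise, so the same functions serve the
deterministic point estimates and the vectorized Monte Carlo engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import ConfigurationError, DomainError, RouteError, ToxicityTableError

__all__ = [
    "INGESTION",
    "DERMAL",
    "CARCINOGENIC_LIFETIME_YEARS",
    "ExposureProfile",
    "ToxicityReference",
    "DoseResult",
    "default_toxicity",
    "cdi_ingestion",
    "cdi_dermal",
    "hazard_quotient",
    "lifetime_cancer_risk",
    "classify_ltcr",
]

INGESTION = "ingestion"
DERMAL = "dermal"

#: lifetime over which carcinogenic doses are averaged (years)
CARCINOGENIC_LIFETIME_YEARS = 70.0

#: acceptable lifetime-cancer-risk band
LTCR_ACCEPTABLE = (1e-6, 1e-4)

# exposure-factor fields that may be scalars or DistributionSpecs
_STOCHASTIC_FIELDS = ("ir_w", "ef_r", "ed", "bw", "sa", "k_p", "et")


@dataclass(frozen=True)
class ExposureProfile:
    """Population-specific exposure factors.

    Each factor is either a point value or a
    :class:`~aquarisk.distributions.DistributionSpec` (for Monte Carlo use).
    ``at_r`` may be left ``None``, in which case the averaging-time convention
    is applied per endpoint (ED × 365 for hazard quotients, 70 × 365 for
    cancer risk).
    """

    name: str
    ir_w: Any          # water intake, L/day
    ef_r: Any          # exposure frequency, days/year
    ed: Any            # exposure duration, years
    bw: Any            # body weight, kg
    at_r: float | None = None   # averaging time, days
    sa: Any = 18000.0  # exposed skin area, cm^2
    k_p: Any = 0.001   # dermal permeability coefficient, cm/h
    et: Any = 0.58     # water exposure time, h/day
    cf: float = 0.001  # unit conversion, L/cm^3

    def __post_init__(self) -> None:
        for fname in (*_STOCHASTIC_FIELDS, "cf"):
            v = getattr(self, fname)
            if v is None and fname in ("sa", "k_p", "et"):
                continue
            if isinstance(v, (int, float)) and not v > 0:
                raise DomainError(f"exposure factor {fname} must be positive")
        if self.at_r is not None and not self.at_r > 0:
            raise DomainError("at_r must be positive when given")

    def factor_mean(self, fname: str) -> float:
        """Point value, or the analytic mean if the factor is a distribution."""
        v = getattr(self, fname)
        return v.mean() if hasattr(v, "mean") and not isinstance(v, (int, float)) else float(v)

    def noncarcinogenic(self) -> "ExposureProfile":
        """Copy with AT_r = ED × 365 days (point ED required)."""
        return replace(self, at_r=self.factor_mean("ed") * 365.0)

    def carcinogenic(self) -> "ExposureProfile":
        """Copy with AT_r = 70 years × 365 days."""
        return replace(self, at_r=CARCINOGENIC_LIFETIME_YEARS * 365.0)

    def to_dict(self) -> dict:
        out = {"name": self.name}
        for fname in (*_STOCHASTIC_FIELDS, "at_r", "cf"):
            v = getattr(self, fname)
            out[fname] = v.to_dict() if hasattr(v, "to_dict") else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ExposureProfile":
        from .distributions import DistributionSpec

        kwargs = {}
        for k, v in d.items():
            if isinstance(v, dict) and "family" in v:
                kwargs[k] = DistributionSpec.from_dict(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


def default_adult_profile() -> ExposureProfile:
    """Resident adult: IR 2 L/day, EF 350 d/y, ED 30 y, BW 70 kg."""
    return ExposureProfile("adult", ir_w=2.0, ef_r=350.0, ed=30.0, bw=70.0,
                           sa=18000.0, k_p=0.001, et=0.58)


def default_child_profile() -> ExposureProfile:
    """Resident child: IR 1 L/day, EF 350 d/y, ED 6 y, BW 15 kg."""
    return ExposureProfile("child", ir_w=1.0, ef_r=350.0, ed=6.0, bw=15.0,
                           sa=6600.0, k_p=0.001, et=1.0)


@dataclass(frozen=True)
class ToxicityReference:
    """Per-metal reference doses (µg/kg·day) and oral slope factors ((mg/kg·day)⁻¹).

    Absent entries raise :class:`ToxicityTableError` on query — a metal
    without an RfD cannot be screened, which is different from zero risk.
    """

    rfd_ingestion: dict[str, float] = field(default_factory=dict)
    rfd_dermal: dict[str, float] = field(default_factory=dict)
    slope_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.rfd_ingestion, self.rfd_dermal, self.slope_factor):
            for metal, v in table.items():
                if not v > 0:
                    raise DomainError(f"toxicity value for {metal} must be positive")

    def rfd(self, metal: str, route: str) -> float:
        if route == DERMAL and metal in self.rfd_dermal:
            return self.rfd_dermal[metal]
        if metal in self.rfd_ingestion:
            # dermal falls back to the oral RfD unless a specific value is set
            return self.rfd_ingestion[metal]
        raise ToxicityTableError(f"no reference dose for {metal} ({route})")

    def sf(self, metal: str) -> float:
        if metal not in self.slope_factor:
            raise ToxicityTableError(f"no slope factor for {metal}")
        return self.slope_factor[metal]

    def has_rfd(self, metal: str) -> bool:
        return metal in self.rfd_ingestion or metal in self.rfd_dermal

    def has_sf(self, metal: str) -> bool:
        return metal in self.slope_factor


def default_toxicity(pb_rfd_printed: bool = False) -> ToxicityReference:
    """Default toxicity tables.

    RfDs (µg/kg·day): Al 1000, Cr 1500, Fe 700, Mn 140, Ni 20.  Pb defaults
    to 1.4 µg/kg·day — the magnitude consistent with reported Pb hazard
    quotients — with the alternative 140 selectable via ``pb_rfd_printed``.
    Oral slope factors ((mg/kg·day)⁻¹): Ni 1.7, Pb 0.0085, Cr 0.5.
    """
    return ToxicityReference(
        rfd_ingestion={
            "Al": 1000.0,
            "Cr": 1500.0,
            "Fe": 700.0,
            "Mn": 140.0,
            "Ni": 20.0,
            "Pb": 140.0 if pb_rfd_printed else 1.4,
        },
        slope_factor={"Ni": 1.7, "Pb": 0.0085, "Cr": 0.5},
    )


@dataclass
class DoseResult:
    """A chronic daily intake (µg/kg·day) for one route.

    ``cdi`` is a scalar for point evaluation or an array under Monte Carlo.
    """

    cdi: Any
    route: str
    metal: str | None = None
    population: str | None = None

    def __post_init__(self) -> None:
        if self.route not in (INGESTION, DERMAL):
            raise RouteError(f"unknown route {self.route!r}")
        if np.any(np.asarray(self.cdi) < 0):
            raise DomainError("CDI must be non-negative")


def _resolve(value, what: str):
    if value is None:
        raise ConfigurationError(f"{what} is required but not configured")
    return value


def cdi_ingestion(c, profile: ExposureProfile, *, metal=None, at_r=None) -> DoseResult:
    """Ingestion chronic daily intake (µg/kg·day); element-wise over arrays."""
    if np.any(~np.isfinite(np.asarray(c, dtype=float))) or np.any(np.asarray(c) < 0):
        raise DomainError("concentration must be finite and non-negative")
    at = at_r if at_r is not None else profile.at_r
    if at is None:
        raise ConfigurationError("averaging time AT_r is not set on the profile")
    cdi = c * profile.ir_w * profile.ef_r * profile.ed / (profile.bw * at)
    return DoseResult(cdi, INGESTION, metal=metal, population=profile.name)


def cdi_dermal(c, profile: ExposureProfile, *, metal=None, at_r=None, k_p=None) -> DoseResult:
    """Dermal-contact chronic daily intake (µg/kg·day); element-wise over arrays."""
    if np.any(~np.isfinite(np.asarray(c, dtype=float))) or np.any(np.asarray(c) < 0):
        raise DomainError("concentration must be finite and non-negative")
    at = at_r if at_r is not None else profile.at_r
    if at is None:
        raise ConfigurationError("averaging time AT_r is not set on the profile")
    kp = k_p if k_p is not None else _resolve(profile.k_p, "dermal permeability K_p")
    sa = _resolve(profile.sa, "skin area SA")
    et = _resolve(profile.et, "exposure time ET")
    cdi = (c * sa * kp * profile.ef_r * profile.ed * et * profile.cf
           / (profile.bw * at))
    return DoseResult(cdi, DERMAL, metal=metal, population=profile.name)


def hazard_quotient(dose: DoseResult, tox: ToxicityReference, metal: str | None = None):
    """HQ = CDI / RfD, with the RfD selected by the dose's route."""
    m = metal or dose.metal
    if m is None:
        raise ToxicityTableError("metal must be known to look up a reference dose")
    return dose.cdi / tox.rfd(m, dose.route)


def classify_ltcr(value: float) -> str:
    """Place a cancer-risk value against the acceptable band 1e-6–1e-4."""
    lo, hi = LTCR_ACCEPTABLE
    if value > hi:
        return "above_acceptable"
    if value < lo:
        return "below_acceptable"
    return "acceptable"


def lifetime_cancer_risk(dose: DoseResult, tox: ToxicityReference,
                         metal: str | None = None):
    """LTCR = CDI (mg/kg·day) × SF; ingestion route only.

    Returns ``(ltcr, classification)``; for array doses the classification is
    that of the mean risk.
    """
    if dose.route != INGESTION:
        raise RouteError("lifetime cancer risk is defined for the ingestion route only")
    m = metal or dose.metal
    if m is None:
        raise ToxicityTableError("metal must be known to look up a slope factor")
    # single point of unit conversion: µg/kg·day -> mg/kg·day
    ltcr = dose.cdi / 1000.0 * tox.sf(m)
    return ltcr, classify_ltcr(float(np.mean(ltcr)))
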