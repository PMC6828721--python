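"""Synthetic district datasets with the statistical structure of the field study.

The emulated design: two districts (Atan, Iju), each sampled at 9 hand-dug
wells and 9 boreholes, three replicate measurements per location — 108
samples from 36 locations.  Concentrations are generated from truncated
lognormals whose truncated means match the published per-district means and
whose bounds match the published ranges; replicate scatter is multiplicative
noise at 5% CV around a location mean, mimicking triplicate instrument
readings.  A single master seed drives hashed per-stratum substreams, so a
dataset is byte-reproducible and strata are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import fit_truncated_lognormal
from .errors import DomainError, FeasibilityError
from .exposure import ExposureProfile, default_adult_profile, default_child_profile
from .samples import MEASURED, NOT_DETECTED, SOURCE_TYPES, WaterSample
from .seeding import substream

__all__ = [
    "two_source_mixture",
    "ParamTarget",
    "DistrictSpec",
    "default_district_specs",
    "generate_district_dataset",
    "generate_study_dataset",
    "default_exposure_profiles",
]

#: CV of replicate-level multiplicative noise around a location mean
REPLICATE_CV = 0.05

#: default CV used to pick concentration SDs where only a mean is published
DEFAULT_CONCENTRATION_CV = 0.45


@dataclass(frozen=True)
class ParamTarget:
    """Target min/max/mean/sd for one parameter in one stratum."""

    min: float
    max: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise DomainError("target range must have min < max")
        if not self.min <= self.mean <= self.max:
            raise FeasibilityError(
                f"target mean {self.mean} outside [{self.min}, {self.max}]"
            )
        if self.sd < 0:
            raise DomainError("target sd must be non-negative")


@dataclass
class DistrictSpec:
    """Generator specification for one district.

    ``targets`` maps (parameter, source_type) to a :class:`ParamTarget`;
    ``not_detected`` maps a parameter to the source types where it is below
    the instrument's reach and is emitted as an ND flag instead of a value.
    """

    name: str
    targets: dict[tuple[str, str], ParamTarget] = field(default_factory=dict)
    not_detected: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_locations: int = 9
    n_replicates: int = 3
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)

    def __post_init__(self) -> None:
        if self.n_locations < 1 or self.n_replicates < 1:
            raise DomainError("counts must be >= 1")

    def parameters(self) -> list[str]:
        seen: list[str] = []
        for (p, _src) in self.targets:
            if p not in seen:
                seen.append(p)
        for p in self.not_detected:
            if p not in seen:
                seen.append(p)
        return seen

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_locations": self.n_locations,
            "n_replicates": self.n_replicates,
            "bbox": list(self.bbox),
            "not_detected": {p: list(s) for p, s in self.not_detected.items()},
            "targets": {
                f"{p}/{src}": [t.min, t.max, t.mean, t.sd]
                for (p, src), t in self.targets.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistrictSpec":
        targets = {}
        for key, (mn, mx, mean, sd) in d["targets"].items():
            p, src = key.split("/")
            targets[(p, src)] = ParamTarget(mn, mx, mean, sd)
        return cls(
            name=d["name"], targets=targets,
            not_detected={p: tuple(s) for p, s in d.get("not_detected", {}).items()},
            n_locations=d.get("n_locations", 9),
            n_replicates=d.get("n_replicates", 3),
            bbox=tuple(d.get("bbox", (0.0, 0.0, 1000.0, 1000.0))),
        )


def _both(targets: dict, param: str, mn, mx, mean, sd=None) -> None:
    if sd is None:
        sd = DEFAULT_CONCENTRATION_CV * mean
    for src in SOURCE_TYPES:
        targets[(param, src)] = ParamTarget(mn, mx, mean, sd)


def default_district_specs() -> dict[str, DistrictSpec]:
    """The two study districts with the published ranges and means.

    Metals are in µg/L; TDS/Ca/Mg in mg/L; EC in the units the source survey prints.
    Where a parameter's SD is published it is used; metal SDs default to a
    45% CV.  Cu and Cd were never detected; Cr was absent at Atan and below
    detection in Iju boreholes.
    """
    atan: dict = {}
    _both(atan, "Fe", 1.8, 39.4, 11.0)
    _both(atan, "Mn", 1.0, 4.8, 3.0)
    _both(atan, "Al", 142.0, 2221.0, 1319.0)
    _both(atan, "Ni", 0.4, 5.3, 2.3)
    _both(atan, "Pb", 0.9, 42.0, 8.0)
    _both(atan, "pH", 5.25, 7.65, 6.67, 0.577)
    _both(atan, "EC", 0.04, 0.45, 0.2059, 0.0627)
    _both(atan, "TDS", 163.48, 773.43, 440.056, 187.55)
    _both(atan, "Ca", 26.144, 50.433, 42.328, 6.07)
    _both(atan, "Mg", 55.086, 98.143, 76.461, 10.76)

    iju: dict = {}
    _both(iju, "Fe", 47.3, 239.7, 88.0)
    _both(iju, "Mn", 3.1, 7.0, 4.0)
    _both(iju, "Al", 2031.0, 6230.0, 3906.0)
    _both(iju, "Ni", 2.1, 14.0, 10.0)
    _both(iju, "Pb", 11.7, 427.2, 13.0)
    _both(iju, "Cr", 0.01, 8.8, 3.0)
    _both(iju, "pH", 2.59, 7.23, 5.21, 1.299)
    _both(iju, "EC", 0.1, 1.6, 0.7422, 0.3012)
    _both(iju, "TDS", 152.81, 782.91, 451.419, 221.42)
    _both(iju, "Ca", 56.734, 219.287, 126.301, 40.6)
    _both(iju, "Mg", 45.025, 90.231, 66.344, 11.3)
    del iju[("Cr", "borehole")]

    return {
        "Atan": DistrictSpec(
            "Atan", atan,
            not_detected={"Cr": SOURCE_TYPES, "Cu": SOURCE_TYPES, "Cd": SOURCE_TYPES},
            bbox=(0.0, 0.0, 1000.0, 1000.0),
        ),
        "Iju": DistrictSpec(
            "Iju", iju,
            not_detected={"Cu": SOURCE_TYPES, "Cd": SOURCE_TYPES,
                          "Cr": ("borehole",)},
            bbox=(2000.0, 0.0, 3000.0, 1000.0),
        ),
    }


def _source_prefix(district: str, source_type: str) -> str:
    return district[:2].upper() + ("B" if source_type == "borehole" else "W")


def generate_district_dataset(spec: DistrictSpec, seed: int) -> list[WaterSample]:
    """Generate locations × replicates samples per source type.

    Location means are drawn from a truncated lognormal whose truncated mean
    matches the stratum target; replicate values multiply the location mean
    by lognormal noise with unit mean and 5% CV, then clip to the target
    range.  Deterministic for a fixed (spec, seed).
    """
    noise_sigma = float(np.sqrt(np.log1p(REPLICATE_CV**2)))
    samples: list[WaterSample] = []
    for source_type in SOURCE_TYPES:
        prefix = _source_prefix(spec.name, source_type)
        rng_xy = substream(seed, spec.name, source_type, "__coords__")
        x0, y0, x1, y1 = spec.bbox
        xs = rng_xy.uniform(x0, x1, spec.n_locations)
        ys = rng_xy.uniform(y0, y1, spec.n_locations)

        per_param: dict[str, np.ndarray] = {}
        nd_params: list[str] = [
            p for p, sources in spec.not_detected.items() if source_type in sources
        ]
        for (param, src), target in spec.targets.items():
            if src != source_type or param in nd_params:
                continue
            dist = fit_truncated_lognormal(
                target.mean, target.sd, target.min, target.max
            )
            rng_p = substream(seed, spec.name, source_type, param)
            loc_means = dist.sample(spec.n_locations, rng_p)
            noise = np.exp(
                rng_p.normal(-0.5 * noise_sigma**2, noise_sigma,
                             (spec.n_locations, spec.n_replicates))
            )
            vals = np.clip(loc_means[:, None] * noise, target.min, target.max)
            if param == "pH":
                vals = np.clip(vals, 0.0, 14.0)
            per_param[param] = vals

        for i in range(spec.n_locations):
            for r in range(spec.n_replicates):
                values = {p: float(v[i, r]) for p, v in per_param.items()}
                flags = {p: MEASURED for p in values}
                flags.update({p: NOT_DETECTED for p in nd_params})
                samples.append(
                    WaterSample(
                        location_id=f"{prefix}{i + 1}",
                        district=spec.name,
                        source_type=source_type,
                        replicate=r + 1,
                        x=float(xs[i]),
                        y=float(ys[i]),
                        values=values,
                        detection_flags=flags,
                    )
                )
    return samples


def generate_study_dataset(seed: int, specs=None) -> list[WaterSample]:
    """Both default districts in one list: the full 108-sample design."""
    specs = specs or default_district_specs()
    out: list[WaterSample] = []
    for name in sorted(specs):
        out.extend(generate_district_dataset(specs[name], seed))
    return out


def two_source_mixture(
    n_obs: int = 18,
    n_vars: int = 10,
    seed: int = 0,
    signal: float = 0.9,
    noise: float = 0.5,
    dominant_noise: float = 0.1,
):
    """Two-latent-source mixture with known loadings, for factor recovery.

    The first half of the variables loads on source 1, the second half on
    source 2 (weight ``signal``), plus independent noise at scale ``noise``.
    The first variable of each block is the *marker* of its source: its noise
    is reduced to ``dominant_noise``, making it the cleanest tracer and
    therefore the dominant contributor to its factor (after the correlation
    standardization a larger raw weight would not survive, but a better
    signal-to-noise ratio does).  Emulates a water-quality matrix driven by
    two pollution sources.  Returns ``(data, planted)`` where ``planted``
    maps each variable name to its source index (0 or 1).
    """
    if n_vars < 2 or n_obs < 3:
        raise DomainError("mixture needs >= 2 variables and >= 3 observations")
    rng = substream(seed, "two_source_mixture")
    factors = rng.normal(size=(n_obs, 2))
    half = n_vars // 2
    loadings = np.zeros((n_vars, 2))
    loadings[:half, 0] = signal
    loadings[half:, 1] = signal
    scales = np.full(n_vars, noise)
    scales[0] = dominant_noise
    if half < n_vars:
        scales[half] = dominant_noise
    data = factors @ loadings.T + rng.normal(size=(n_obs, n_vars)) * scales
    names = [f"V{j + 1}" for j in range(n_vars)]
    planted = {name: (0 if j < half else 1) for j, name in enumerate(names)}
    return pd.DataFrame(data, columns=names), planted


def default_exposure_profiles() -> dict[str, ExposureProfile]:
    """Adult and child exposure profiles (point defaults, MC-overridable).

    The source survey's supplementary exposure table is not published; these are
    back-calculated resident defaults — adult 2 L/day over 70 kg, child
    1 L/day over 15 kg, both at 350 days/year — kept configurable.
    """
    return {"adult": default_adult_profile(), "child": default_child_profile()}
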