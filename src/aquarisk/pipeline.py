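"""End-to-end assessment: data → descriptives → risk simulation → reports.

``run_full_assessment`` drives every stage behind one configuration object
and writes a directory bundle of CSV/ASC outputs plus a machine-readable
manifest (config hash, seed, stage row counts, warnings such as censoring
substitutions or metals that could not be screened).  The bundle is
deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .apportionment import (
    extract_factors,
    observation_contributions,
    variable_contributions,
)
from .distributions import DistributionSpec, fit_lognormal_from_summary
from .errors import ConfigurationError, EmptyStratumError
from .exposure import ExposureProfile, ToxicityReference, default_toxicity
from .idw import RasterGrid, idw_interpolate, write_ascii_grid
from .montecarlo import simulate_risk
from .samples import (
    DISTRICTS,
    METALS,
    NOT_DETECTED,
    SOURCE_TYPES,
    GuidelineTable,
    default_guidelines,
    filter_samples,
    location_means,
    read_sample_table,
    summarize,
    violation_rate,
    write_sample_table,
)
from .seeding import subseed, substream
from .sensitivity import contribution_analysis
from .synthetic import (
    DistrictSpec,
    default_district_specs,
    default_exposure_profiles,
    generate_study_dataset,
)

__all__ = ["RunConfig", "run_full_assessment"]

ALL_STAGES = ("describe", "simulate", "sensitivity", "apportion", "map")

#: thresholds against which exceedance fractions are reported
HQ_THRESHOLD = 1.0
LTCR_THRESHOLD = 1e-4

#: default exposure-factor uncertainty used by the sensitivity stage,
#: expressed relative to the profile's point value
SENSITIVITY_FACTOR_SPECS = {
    "ir_w": ("normal", 0.075),   # intake rate: mild measurement spread
    "ef_r": ("uniform", None),   # exposure frequency: 250-365 days/year
    "ed": ("normal", 0.05),
    "bw": ("normal", 0.15),
}


@dataclass
class RunConfig:
    """Configuration for one assessment run.

    Exactly one input mode: ``input_path`` (a sample CSV) or synthetic
    generation from ``district_specs`` with ``generator_seed``.
    """

    input_path: str | None = None
    district_specs: dict[str, DistrictSpec] | None = None
    generator_seed: int = 0
    profiles: dict[str, ExposureProfile] = field(default_factory=default_exposure_profiles)
    toxicity: ToxicityReference = field(default_factory=default_toxicity)
    guidelines: GuidelineTable = field(default_factory=default_guidelines)
    n_iterations: int = 10_000
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str = "aquarisk_out"
    idw_power: float = 2.0
    idw_cellsize: float = 50.0
    conc_dist: DistributionSpec | None = None  # override for single-metal runs

    def __post_init__(self) -> None:
        if self.input_path is not None and self.district_specs is not None:
            raise ConfigurationError("choose one input mode: file or synthetic spec")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")

    def validate(self) -> None:
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigurationError(f"input file {self.input_path!r} does not exist")

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "district_specs": (
                {k: v.to_dict() for k, v in self.district_specs.items()}
                if self.district_specs is not None else None
            ),
            "generator_seed": self.generator_seed,
            "profiles": {k: v.to_dict() for k, v in self.profiles.items()},
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "stages": list(self.stages),
            "out_dir": self.out_dir,
            "idw_power": self.idw_power,
            "idw_cellsize": self.idw_cellsize,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = dict(d)
        if kwargs.get("district_specs"):
            kwargs["district_specs"] = {
                k: DistrictSpec.from_dict(v)
                for k, v in kwargs["district_specs"].items()
            }
        if kwargs.get("profiles"):
            kwargs["profiles"] = {
                k: ExposureProfile.from_dict(v) for k, v in kwargs["profiles"].items()
            }
        if kwargs.get("stages"):
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_samples(config: RunConfig, warnings: list[str]):
    if config.input_path is not None:
        return read_sample_table(config.input_path), False
    specs = config.district_specs or default_district_specs()
    return generate_study_dataset(config.generator_seed, specs), True


def _describe(samples, guidelines: GuidelineTable) -> pd.DataFrame:
    rows = []
    params = sorted({p for s in samples for p in s.detection_flags})
    for district in DISTRICTS:
        for source_type in SOURCE_TYPES:
            stratum = filter_samples(samples, district, source_type)
            if not stratum:
                continue
            for param in params:
                try:
                    st = summarize(stratum, param)
                except EmptyStratumError:
                    continue
                row = {
                    "district": district, "source_type": source_type,
                    "parameter": param, "n": st.n, "min": st.min, "max": st.max,
                    "mean": st.mean, "sd": st.sd,
                }
                for authority in ("WHO", "NSDWQ"):
                    key = f"pct_above_{authority}"
                    if (param, authority) in guidelines:
                        row[key] = violation_rate(
                            stratum, param, guidelines.get(param, authority)
                        )
                    else:
                        row[key] = float("nan")
                rows.append(row)
    return pd.DataFrame(rows)


def _measured_metals(samples) -> list[str]:
    present = []
    for m in METALS:
        if any(m in s.values and s.flag(m) == "measured" for s in samples):
            present.append(m)
    return present


def _nd_metals(samples) -> list[str]:
    out = []
    for m in METALS:
        flags = [s.flag(m) for s in samples if m in s.detection_flags]
        if flags and all(f == NOT_DETECTED for f in flags):
            out.append(m)
    return out


def _simulate(samples, config: RunConfig, warnings: list[str]) -> pd.DataFrame:
    rows = []
    for district in DISTRICTS:
        for source_type in SOURCE_TYPES:
            stratum = filter_samples(samples, district, source_type)
            if not stratum:
                continue
            for nd in _nd_metals(stratum):
                warnings.append(
                    f"{district}/{source_type}: {nd} not detected (ND); "
                    "excluded from risk simulation"
                )
            for metal in _measured_metals(stratum):
                st = summarize(stratum, metal)
                conc = config.conc_dist or fit_lognormal_from_summary(st.mean, max(st.sd, 1e-12))
                for pop, profile in sorted(config.profiles.items()):
                    cells = []
                    if config.toxicity.has_rfd(metal):
                        cells.append(("HQ", "ingestion", HQ_THRESHOLD))
                        cells.append(("HQ", "dermal", HQ_THRESHOLD))
                    else:
                        warnings.append(
                            f"{district}/{source_type}: {metal} not screened "
                            "(no reference dose)"
                        )
                    if config.toxicity.has_sf(metal):
                        cells.append(("LTCR", "ingestion", LTCR_THRESHOLD))
                    for endpoint, route, threshold in cells:
                        seed = subseed(config.seed, district, source_type,
                                       metal, pop, endpoint, route)
                        dist = simulate_risk(
                            conc, profile, config.toxicity, metal, route=route,
                            endpoint=endpoint, n=config.n_iterations, seed=seed,
                            district=district, source_type=source_type,
                        )
                        s = dist.summary()
                        rows.append({
                            "district": district, "source_type": source_type,
                            "metal": metal, "population": pop, "route": route,
                            "endpoint": endpoint, "n": dist.n,
                            "mean": s.mean, "sd": s.sd,
                            "p5": s[5.0], "p50": s[50.0], "p90": s[90.0],
                            "p95": s[95.0], "p99": s[99.0], "p99_9": s[99.9],
                            "threshold": threshold,
                            "exceedance_pct": dist.exceedance(threshold),
                        })
    return pd.DataFrame(rows)


def _sensitivity_inputs(profile: ExposureProfile) -> dict[str, DistributionSpec]:
    out = {}
    for fname, (family, rel_sd) in SENSITIVITY_FACTOR_SPECS.items():
        v = profile.factor_mean(fname)
        if family == "uniform":
            out[fname] = DistributionSpec("uniform", (250.0, 365.0))
        else:
            out[fname] = DistributionSpec(
                "normal", (v, rel_sd * v), truncation=(0.2 * v, 2.0 * v)
            )
    return out


def _sensitivity(samples, config: RunConfig) -> pd.DataFrame:
    """Spearman contribution shares for the cancer-risk inputs, per stratum."""
    rows = []
    for district in DISTRICTS:
        for source_type in SOURCE_TYPES:
            stratum = filter_samples(samples, district, source_type)
            if not stratum:
                continue
            metals = [m for m in _measured_metals(stratum)
                      if config.toxicity.has_sf(m)]
            for metal in metals:
                st = summarize(stratum, metal)
                conc = fit_lognormal_from_summary(st.mean, max(st.sd, 1e-12))
                for pop, profile in sorted(config.profiles.items()):
                    rng = substream(config.seed, "sensitivity", district,
                                    source_type, metal, pop)
                    n = config.n_iterations
                    draws = {"C": conc.sample(n, rng)}
                    for fname, spec in _sensitivity_inputs(profile).items():
                        draws[fname] = spec.sample(n, rng)
                    sf = config.toxicity.sf(metal)
                    out = (draws["C"] * draws["ir_w"] * draws["ef_r"]
                           * draws["ed"] * sf
                           / (draws["bw"] * 70.0 * 365.0 * 1000.0))
                    report = contribution_analysis(draws, out)
                    for var, pct in report.ranked():
                        rows.append({
                            "district": district, "source_type": source_type,
                            "metal": metal, "population": pop,
                            "variable": var, "contribution_pct": pct,
                            "spearman_r": report.correlations[var],
                        })
    return pd.DataFrame(rows)


def _district_table(samples, district: str) -> pd.DataFrame:
    """Location × parameter table of replicate means for apportionment.

    A parameter measured in only part of the district (e.g. censored in one
    source type) contributes zeros at its ND locations; parameters with no
    measured values anywhere are dropped.
    """
    stratum = filter_samples(samples, district)
    locations = sorted({s.location_id for s in stratum})
    params = sorted({p for s in stratum for p in s.detection_flags
                     if any(x.flag(p) == "measured" for x in stratum)})
    table = pd.DataFrame(index=locations, columns=params, dtype=float)
    for param in params:
        means = location_means(stratum, param)
        for loc in locations:
            table.loc[loc, param] = means.get(loc, 0.0)
    return table


def _apportion(samples, out_dir: Path) -> dict[str, float]:
    retained = {}
    for district in DISTRICTS:
        table = _district_table(samples, district)
        if table.empty or len(table) < 3:
            continue
        table = table.loc[:, table.std(ddof=1) > 0]
        model = extract_factors(table, n_factors=3)
        ev = pd.DataFrame({
            "factor": model.loadings.columns,
            "eigenvalue": model.eigenvalues,
            "explained_pct": model.explained_variance_pct,
            "cumulative_pct": model.cumulative_variance_pct,
        })
        ev.to_csv(out_dir / f"apportion_{district}_eigenvalues.csv", index=False)
        model.loadings.to_csv(out_dir / f"apportion_{district}_loadings.csv")
        variable_contributions(model).to_csv(
            out_dir / f"apportion_{district}_variable_contributions.csv")
        observation_contributions(model).to_csv(
            out_dir / f"apportion_{district}_observation_contributions.csv")
        retained[district] = model.retained_variance_pct()
    return retained


def _maps(samples, config: RunConfig, out_dir: Path) -> list[str]:
    written = []
    for district in DISTRICTS:
        stratum = filter_samples(samples, district)
        if not stratum:
            continue
        xs = [s.x for s in stratum]
        ys = [s.y for s in stratum]
        pad = config.idw_cellsize
        bbox = (min(xs) - pad, min(ys) - pad, max(xs) + pad, max(ys) + pad)
        params = sorted({p for s in stratum for p in s.detection_flags})
        coords = {s.location_id: (s.x, s.y) for s in stratum}
        for param in params:
            means = location_means(stratum, param)
            if len(means) < 1:
                continue
            points = [(coords[loc][0], coords[loc][1], v)
                      for loc, v in sorted(means.items())]
            grid = RasterGrid.from_bbox(bbox, config.idw_cellsize)
            result = idw_interpolate(points, grid, power=config.idw_power)
            name = f"map_{district}_{param}.asc"
            write_ascii_grid(result, out_dir / name)
            written.append(name)
    return written


def run_full_assessment(config: RunConfig) -> dict:
    """Run every enabled stage; returns the manifest dictionary.

    Outputs land in ``config.out_dir``: the dataset CSV, per-stratum summary,
    risk tables in the adult/child percentile layout, sensitivity tornado
    rows, apportionment CSVs, one ``.asc`` grid per (district, parameter),
    and ``manifest.json``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    samples, generated = _load_samples(config, warnings)
    write_sample_table(samples, out_dir / "dataset.csv")

    manifest: dict = {
        "package": "aquarisk",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "generator_seed": config.generator_seed if generated else None,
        "input": "synthetic" if generated else config.input_path,
        "n_samples": len(samples),
        "stages": {},
        "warnings": warnings,
    }

    if "describe" in config.stages:
        df = _describe(samples, config.guidelines)
        df.to_csv(out_dir / "summary.csv", index=False)
        manifest["stages"]["describe"] = {"rows": len(df)}

    if "simulate" in config.stages:
        df = _simulate(samples, config, warnings)
        df.to_csv(out_dir / "risk_tables.csv", index=False)
        manifest["stages"]["simulate"] = {
            "rows": len(df), "n_iterations": config.n_iterations,
        }

    if "sensitivity" in config.stages:
        df = _sensitivity(samples, config)
        df.to_csv(out_dir / "sensitivity.csv", index=False)
        manifest["stages"]["sensitivity"] = {"rows": len(df)}

    if "apportion" in config.stages:
        retained = _apportion(samples, out_dir)
        manifest["stages"]["apportion"] = {
            "retained_variance_pct": retained,
        }

    if "map" in config.stages:
        written = _maps(samples, config, out_dir)
        manifest["stages"]["map"] = {"grids": len(written)}

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
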