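"""Water-sample domain types, CSV I/O, descriptive statistics, guideline accounting.

Canonical units: metals in µg/L, TDS/Ca/Mg in mg/L, EC in µS/cm, pH unitless.
CSV columns may carry a unit annotation in square brackets (``Pb[mg/L]``);
mg/L metal columns are converted to µg/L on ingest.  Non-detects are the
token ``ND``; censored values the token ``<x`` with detection limit ``x``.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, EmptyStratumError, IntegrityError, ParseError

__all__ = [
    "MEASURED",
    "BELOW_DETECTION",
    "NOT_DETECTED",
    "METALS",
    "WaterSample",
    "SummaryStats",
    "GuidelineTable",
    "default_guidelines",
    "read_sample_table",
    "write_sample_table",
    "filter_samples",
    "location_means",
    "summarize",
    "violation_rate",
    "classify_correlation",
]

MEASURED = "measured"
BELOW_DETECTION = "below_detection"
NOT_DETECTED = "not_detected"

#: parameters treated as metals (canonical unit µg/L)
METALS = ("Pb", "Cr", "Ni", "Fe", "Mn", "Al", "Cu", "Cd")

DISTRICTS = ("Atan", "Iju")
SOURCE_TYPES = ("borehole", "well")

_CANONICAL_UNITS = {"ug/L": 1.0, "µg/L": 1.0, "mg/L": 1000.0}


@dataclass
class WaterSample:
    """One replicate measurement at one sampling location."""

    location_id: str
    district: str
    source_type: str
    replicate: int
    x: float
    y: float
    values: dict[str, float] = field(default_factory=dict)
    detection_flags: dict[str, str] = field(default_factory=dict)
    detection_limits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.district not in DISTRICTS:
            raise DomainError(f"unknown district {self.district!r}")
        if self.source_type not in SOURCE_TYPES:
            raise DomainError(f"unknown source type {self.source_type!r}")
        if self.replicate < 1:
            raise DomainError("replicate index must be >= 1")
        for param, v in self.values.items():
            flag = self.detection_flags.get(param, MEASURED)
            if flag == MEASURED:
                if not math.isfinite(v) or v < 0:
                    raise DomainError(
                        f"measured {param} = {v!r} must be finite and non-negative"
                    )
                if param == "pH" and not 0 <= v <= 14:
                    raise DomainError(f"pH = {v} outside [0, 14]")

    def flag(self, param: str) -> str:
        return self.detection_flags.get(param, MEASURED)


@dataclass(frozen=True)
class SummaryStats:
    """min/max/mean/sd over the measured values of one stratum."""

    n: int
    min: float
    max: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not (self.min <= self.mean <= self.max) or self.sd < 0:
            raise DomainError("summary statistics violate min <= mean <= max, sd >= 0")


class GuidelineTable:
    """(parameter, authority) -> limit, in canonical units.

    Authorities follow the survey's comparisons: ``WHO``, ``NSDWQ`` and the
    most-desirable-limit tier ``WHO_MDL`` used for hardness indicators.
    Unknown entries are absent, never zero.
    """

    def __init__(self, limits: dict[tuple[str, str], float] | None = None):
        self._limits: dict[tuple[str, str], float] = {}
        for key, v in (limits or {}).items():
            self.set(key[0], key[1], v)

    def set(self, parameter: str, authority: str, limit: float) -> None:
        if not limit > 0:
            raise DomainError("guideline limits must be positive")
        self._limits[(parameter, authority)] = float(limit)

    def get(self, parameter: str, authority: str) -> float:
        return self._limits[(parameter, authority)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._limits

    def items(self):
        return self._limits.items()


def default_guidelines() -> GuidelineTable:
    """Drinking-water limits used for exceedance accounting (config data).

    Metals in µg/L; TDS/Ca/Mg in mg/L; EC in µS/cm.
    """
    g = GuidelineTable()
    for param, who, nsdwq in [
        ("Pb", 10.0, 10.0),
        ("Cr", 50.0, 50.0),
        ("Ni", 70.0, 20.0),
        ("Fe", 300.0, 300.0),
        ("Mn", 400.0, 200.0),
        ("Al", 200.0, 200.0),
        ("Cd", 3.0, 3.0),
        ("Cu", 2000.0, 1000.0),
    ]:
        g.set(param, "WHO", who)
        g.set(param, "NSDWQ", nsdwq)
    g.set("TDS", "WHO", 1000.0)
    g.set("EC", "WHO", 1400.0)
    g.set("Ca", "WHO_MDL", 50.0)
    g.set("Ca", "NSDWQ", 75.0)
    g.set("Mg", "WHO_MDL", 50.0)
    g.set("Mg", "NSDWQ", 20.0)
    return g


# ---------------------------------------------------------------------------
# table I/O

_HEADER_RE = re.compile(r"^(?P<name>[^\[\]]+?)\s*(\[(?P<unit>[^\[\]]+)\])?$")
_ID_COLUMNS = ("location_id", "district", "source_type", "replicate", "x", "y")


def _parse_header(columns: list[str]) -> list[tuple[str, str, float]]:
    """-> [(raw column, parameter name, scale-to-canonical), ...]."""
    out = []
    for col in columns:
        if col in _ID_COLUMNS:
            continue
        m = _HEADER_RE.match(col.strip())
        if m is None:
            raise ParseError(f"cannot parse column header {col!r}")
        name, unit = m.group("name").strip(), m.group("unit")
        scale = 1.0
        if unit is not None:
            unit = unit.strip()
            if name in METALS:
                if unit not in _CANONICAL_UNITS:
                    raise ParseError(f"unresolvable unit {unit!r} for column {col!r}")
                scale = _CANONICAL_UNITS[unit]
            # non-metal units are annotations only; values kept as printed
        out.append((col, name, scale))
    return out


def read_sample_table(path_or_buffer) -> list[WaterSample]:
    """Read a per-replicate sample CSV into WaterSample records.

    ``ND`` cells become not_detected; ``<x`` cells become below_detection
    with detection limit ``x`` (unit-converted like a measured value).
    Duplicate (location_id, replicate) pairs raise IntegrityError.
    """
    if isinstance(path_or_buffer, (str, Path)):
        with open(path_or_buffer, newline="", encoding="utf-8") as fh:
            return read_sample_table(fh)
    reader = csv.DictReader(path_or_buffer)
    if reader.fieldnames is None:
        raise ParseError("missing header row")
    for col in _ID_COLUMNS:
        if col not in reader.fieldnames:
            raise ParseError(f"missing required column {col!r}")
    params = _parse_header(list(reader.fieldnames))
    samples: list[WaterSample] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(reader, start=2):
        try:
            replicate = int(row["replicate"])
            x, y = float(row["x"]), float(row["y"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed identity cell in row {i}: {exc}") from exc
        key = (row["location_id"], replicate)
        if key in seen:
            raise IntegrityError(f"duplicate (location, replicate) pair {key}")
        seen.add(key)
        values, flags, limits = {}, {}, {}
        for col, name, scale in params:
            cell = (row.get(col) or "").strip()
            if cell == "":
                continue
            if cell.upper() == "ND":
                flags[name] = NOT_DETECTED
                continue
            if cell.startswith("<"):
                try:
                    dl = float(cell[1:])
                except ValueError as exc:
                    raise ParseError(
                        f"malformed censored cell {cell!r} at row {i}, column {col!r}"
                    ) from exc
                flags[name] = BELOW_DETECTION
                limits[name] = dl * scale
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"malformed numeric cell {cell!r} at row {i}, column {col!r}"
                ) from exc
            values[name] = v * scale
            flags[name] = MEASURED
        samples.append(
            WaterSample(row["location_id"], row["district"], row["source_type"],
                        replicate, x, y, values, flags, limits)
        )
    return samples


def write_sample_table(samples: list[WaterSample], path_or_buffer) -> None:
    """Write samples back to the canonical CSV layout (µg/L metal columns)."""
    if isinstance(path_or_buffer, (str, Path)):
        with open(path_or_buffer, "w", newline="", encoding="utf-8") as fh:
            write_sample_table(samples, fh)
            return
    params: list[str] = []
    for s in samples:
        for p in list(s.values) + list(s.detection_flags):
            if p not in params:
                params.append(p)
    header = list(_ID_COLUMNS) + [
        f"{p}[ug/L]" if p in METALS else p for p in params
    ]
    writer = csv.writer(path_or_buffer)
    writer.writerow(header)
    for s in samples:
        row = [s.location_id, s.district, s.source_type, s.replicate,
               repr(s.x), repr(s.y)]
        for p in params:
            flag = s.detection_flags.get(p)
            if flag == NOT_DETECTED:
                row.append("ND")
            elif flag == BELOW_DETECTION:
                row.append(f"<{s.detection_limits[p]!r}")
            elif p in s.values:
                row.append(repr(s.values[p]))
            else:
                row.append("")
        writer.writerow(row)


def samples_to_csv_text(samples: list[WaterSample]) -> str:
    buf = io.StringIO()
    write_sample_table(samples, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# descriptive statistics


def filter_samples(samples, district=None, source_type=None):
    out = samples
    if district is not None:
        out = [s for s in out if s.district == district]
    if source_type is not None:
        out = [s for s in out if s.source_type == source_type]
    return list(out)


def _stratum_values(samples, parameter) -> list[float]:
    """Measured values plus DL/2 substitutes for censored cells."""
    vals = []
    for s in samples:
        flag = s.flag(parameter)
        if parameter in s.values and flag == MEASURED:
            vals.append(s.values[parameter])
        elif flag == BELOW_DETECTION:
            vals.append(s.detection_limits[parameter] / 2.0)
    return vals


def summarize(samples, parameter, district=None, source_type=None, ddof=1) -> SummaryStats:
    """Descriptive statistics for one parameter in one stratum.

    Censored (below-detection) values enter at half the detection limit;
    non-detects are excluded.  ``ddof=1`` gives the sample SD convention;
    ``ddof=0`` the population convention.
    """
    stratum = filter_samples(samples, district, source_type)
    vals = _stratum_values(stratum, parameter)
    if not vals:
        raise EmptyStratumError(
            f"no measured values for {parameter!r} in stratum "
            f"({district!r}, {source_type!r})"
        )
    arr = np.asarray(vals, dtype=float)
    sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    return SummaryStats(n=arr.size, min=float(arr.min()), max=float(arr.max()),
                        mean=float(arr.mean()), sd=sd)


def location_means(samples, parameter, district=None, source_type=None) -> dict[str, float]:
    """Replicate-averaged value per location (measured + DL/2 censored)."""
    stratum = filter_samples(samples, district, source_type)
    acc: dict[str, list[float]] = {}
    for s in stratum:
        flag = s.flag(parameter)
        if parameter in s.values and flag == MEASURED:
            acc.setdefault(s.location_id, []).append(s.values[parameter])
        elif flag == BELOW_DETECTION:
            acc.setdefault(s.location_id, []).append(
                s.detection_limits[parameter] / 2.0
            )
    return {loc: float(np.mean(v)) for loc, v in acc.items()}


def violation_rate(samples, parameter, limit, district=None, source_type=None) -> float:
    """Percent of locations whose replicate-mean value strictly exceeds ``limit``.

    Replicates are averaged to one value per location first: the source survey's
    per-source percentages (e.g. 4 of 9 boreholes -> 44.44%) are location-level
    ratios.
    """
    means = location_means(samples, parameter, district, source_type)
    if not means:
        raise EmptyStratumError(
            f"no values for {parameter!r} in stratum ({district!r}, {source_type!r})"
        )
    above = sum(1 for v in means.values() if v > limit)
    return 100.0 * above / len(means)


def classify_correlation(r: float) -> str:
    """Strength class of a correlation coefficient by magnitude.

    |r| < 0.5 weak; 0.5 <= |r| < 0.7 moderate; |r| >= 0.7 strong.  Negative
    coefficients are classified by magnitude (the sign is reported separately).
    """
    if not math.isfinite(r) or abs(r) > 1:
        raise DomainError(f"|r| must be <= 1, got {r!r}")
    a = abs(r)
    if a >= 0.7:
        return "strong"
    if a >= 0.5:
        return "moderate"
    return "weak"
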