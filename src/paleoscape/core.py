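"""Shared domain types, isotope/stoichiometry conversions, and table I/O.

Units and conventions used throughout the package:

* Stable-isotope values are per-mil (‰) deviations from a reference
  standard: atmospheric N2 for nitrogen, VPDB for carbon.  Standards have
  δ = 0 by definition.  δ values are carried as plain floats.
* Depths are cm below the sediment surface, intervals half-open
  [top, bottom); the surface is 0 cm at the collection date.
* Coordinates are planar metres (no projection handling); the channel
  "mouth" sits near x = 0 and the "head" at the far end of the axis.
* Carbon/nitrogen content is weight percent; C/N is a *molar* ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# IUPAC standard atomic weights
ATOMIC_WEIGHT_C = 12.011
ATOMIC_WEIGHT_N = 14.007


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CoreSite:
    """A coring location on the estuary grid.

    ``role`` distinguishes the densely sampled *focal* cores (1-cm
    sectioning, used for timeseries and chronologies) from ordinary
    *grid* cores (coarse sectioning, used for mapping).
    """

    site_id: str
    x: float
    y: float
    role: str = "grid"  # "focal" or "grid"
    collection_year: int = 2010

    def __post_init__(self) -> None:
        if self.role not in ("focal", "grid"):
            raise ValueError(f"unknown site role {self.role!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for site {self.site_id}")


@dataclass(frozen=True)
class DepthInterval:
    """Half-open depth interval [top, bottom) in cm below the surface."""

    top: float
    bottom: float

    def __post_init__(self) -> None:
        if self.top < 0 or self.bottom < 0:
            raise ValueError("depths must be non-negative")
        if not self.top < self.bottom:
            raise ValueError(f"need top < bottom, got [{self.top}, {self.bottom})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top + self.bottom)

    @property
    def thickness(self) -> float:
        return self.bottom - self.top


@dataclass
class CoreSample:
    """One depth-interval measurement of δ15N, δ13C, C% and N% for a core.

    Missing measurements are ``nan`` and propagate as missing — they are
    never imputed by downstream binning or mapping.
    """

    site_id: str
    interval: DepthInterval
    d15N: float = math.nan
    d13C: float = math.nan
    c_pct: float = math.nan
    n_pct: float = math.nan

    def __post_init__(self) -> None:
        for name in ("c_pct", "n_pct"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def cn_molar(self) -> float:
        """Molar C/N ratio; ``nan`` unless both contents present and N% > 0."""
        if math.isnan(self.c_pct) or math.isnan(self.n_pct) or self.n_pct <= 0:
            return math.nan
        return cn_molar(self.c_pct, self.n_pct)


@dataclass(frozen=True)
class WaterQualityRecord:
    """A monthly water-column observation at a monitoring station."""

    station_id: str
    date: pd.Timestamp
    no3: float  # dissolved nitrate, μM
    salinity: float  # ppt

    def __post_init__(self) -> None:
        if self.no3 < 0:
            raise ValueError("no3 must be >= 0")
        if self.salinity < 0:
            raise ValueError("salinity must be >= 0")


@dataclass(frozen=True)
class EraBin:
    """A half-open calendar-year bin [start_year, end_year)."""

    label: str
    start_year: float
    end_year: float

    def __post_init__(self) -> None:
        if not self.start_year < self.end_year:
            raise ValueError("need start_year < end_year")

    def contains(self, year: float) -> bool:
        return self.start_year <= year < self.end_year


#: The six mapping eras.  Bins are half-open; the most recent bin is extended
#: to 2011 so samples dated exactly 2010 fall inside it.
DEFAULT_ERAS: tuple[EraBin, ...] = (
    EraBin("1726-1839", 1726, 1839),
    EraBin("1839-1885", 1839, 1885),
    EraBin("1885-1951", 1885, 1951),
    EraBin("1951-1963", 1951, 1963),
    EraBin("1963-1981", 1963, 1981),
    EraBin("1981-2010", 1981, 2011),
)


def validate_era_set(eras: Sequence[EraBin]) -> None:
    """Check that a sequence of era bins is contiguous and non-overlapping."""
    for a, b in zip(eras, eras[1:]):
        if a.end_year != b.start_year:
            raise ValueError(f"era bins {a.label!r} and {b.label!r} not contiguous")


def era_for_year(year: float, eras: Sequence[EraBin]) -> EraBin | None:
    for era in eras:
        if era.contains(year):
            return era
    return None


# ---------------------------------------------------------------------------
# conversions


def delta_value(r_sample: float, r_standard: float) -> float:
    """Per-mil delta value δ = (R_sample / R_standard − 1) × 1000.

    R is the abundance ratio of the rare to the common isotope
    (15N/14N against atmospheric N2; 13C/12C against VPDB).
    """
    if r_standard <= 0:
        raise ValueError(f"standard ratio must be positive, got {r_standard}")
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_value`: recover the sample abundance ratio."""
    if r_standard <= 0:
        raise ValueError(f"standard ratio must be positive, got {r_standard}")
    return (delta / 1000.0 + 1.0) * r_standard


def cn_molar(c_pct: float, n_pct: float) -> float:
    """Molar C/N ratio from weight-percent contents."""
    if n_pct <= 0:
        raise ValueError(f"n_pct must be positive, got {n_pct}")
    return (c_pct / ATOMIC_WEIGHT_C) / (n_pct / ATOMIC_WEIGHT_N)


# ---------------------------------------------------------------------------
# core-sample tables

CORE_TABLE_COLUMNS = [
    "site_id",
    "x",
    "y",
    "role",
    "collection_year",
    "top_cm",
    "bottom_cm",
    "d15N",
    "d13C",
    "c_pct",
    "n_pct",
]

_REQUIRED_CORE_COLUMNS = [
    "site_id",
    "x",
    "y",
    "top_cm",
    "bottom_cm",
    "d15N",
    "d13C",
    "c_pct",
    "n_pct",
]

_NUMERIC_CORE_COLUMNS = [
    "x",
    "y",
    "top_cm",
    "bottom_cm",
    "d15N",
    "d13C",
    "c_pct",
    "n_pct",
]


def _fmt(v: float) -> str:
    """Fixed 6-decimal formatting; empty string for missing values."""
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return f"{float(v):.6f}"


def write_core_table(
    samples: Iterable[CoreSample],
    sites: Iterable[CoreSite],
    path: str | Path,
) -> None:
    """Write samples + site metadata as a single comma-delimited table.

    Values are written with six decimal places so a write→read→write cycle
    is byte-stable; missing values are empty fields.
    """
    site_map = {s.site_id: s for s in sites}
    lines = [",".join(CORE_TABLE_COLUMNS)]
    for smp in samples:
        site = site_map[smp.site_id]
        lines.append(
            ",".join(
                [
                    smp.site_id,
                    _fmt(site.x),
                    _fmt(site.y),
                    site.role,
                    str(site.collection_year),
                    _fmt(smp.interval.top),
                    _fmt(smp.interval.bottom),
                    _fmt(smp.d15N),
                    _fmt(smp.d13C),
                    _fmt(smp.c_pct),
                    _fmt(smp.n_pct),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_core_table(path: str | Path) -> tuple[list[CoreSample], list[CoreSite]]:
    """Read a core-sample table; returns (samples, unique sites) in file order."""
    df = pd.read_csv(path, dtype={"site_id": str})
    for col in _REQUIRED_CORE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    for col in _NUMERIC_CORE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"data row {row + 1}"
            )
        df[col] = coerced

    sites: dict[str, CoreSite] = {}
    samples: list[CoreSample] = []
    has_role = "role" in df.columns
    has_year = "collection_year" in df.columns
    for _, row in df.iterrows():
        sid = row["site_id"]
        if sid not in sites:
            sites[sid] = CoreSite(
                site_id=sid,
                x=float(row["x"]),
                y=float(row["y"]),
                role=str(row["role"]) if has_role else "grid",
                collection_year=int(row["collection_year"]) if has_year else 2010,
            )
        samples.append(
            CoreSample(
                site_id=sid,
                interval=DepthInterval(float(row["top_cm"]), float(row["bottom_cm"])),
                d15N=float(row["d15N"]) if pd.notna(row["d15N"]) else math.nan,
                d13C=float(row["d13C"]) if pd.notna(row["d13C"]) else math.nan,
                c_pct=float(row["c_pct"]) if pd.notna(row["c_pct"]) else math.nan,
                n_pct=float(row["n_pct"]) if pd.notna(row["n_pct"]) else math.nan,
            )
        )
    return samples, list(sites.values())


# ---------------------------------------------------------------------------
# water-quality tables

WQ_TABLE_COLUMNS = ["station_id", "date", "no3_um", "salinity_ppt"]


def write_water_quality_table(
    records: Iterable[WaterQualityRecord], path: str | Path
) -> None:
    lines = [",".join(WQ_TABLE_COLUMNS)]
    for r in records:
        lines.append(
            ",".join(
                [
                    r.station_id,
                    pd.Timestamp(r.date).strftime("%Y-%m-%d"),
                    _fmt(r.no3),
                    _fmt(r.salinity),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_water_quality_table(path: str | Path) -> list[WaterQualityRecord]:
    df = pd.read_csv(path, dtype={"station_id": str})
    for col in WQ_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    out = []
    for _, row in df.iterrows():
        out.append(
            WaterQualityRecord(
                station_id=row["station_id"],
                date=pd.Timestamp(row["date"]),
                no3=float(row["no3_um"]),
                salinity=float(row["salinity_ppt"]),
            )
        )
    return out


@dataclass(frozen=True)
class AnnualWaterQuality:
    """Annual mean water quality for one station/year; nan when unobserved."""

    station_id: str
    year: int
    no3: float
    salinity: float
    n_months: int


def annual_mean_water_quality(
    records: Iterable[WaterQualityRecord], station: str, year: int
) -> AnnualWaterQuality:
    """Arithmetic mean of the monthly records available for station/year.

    Returns a missing-value result (nan means, n_months = 0) rather than
    raising when the station/year has no observations.
    """
    no3 = []
    sal = []
    for r in records:
        if r.station_id == station and pd.Timestamp(r.date).year == year:
            no3.append(r.no3)
            sal.append(r.salinity)
    if not no3:
        return AnnualWaterQuality(station, year, math.nan, math.nan, 0)
    return AnnualWaterQuality(
        station, year, float(np.mean(no3)), float(np.mean(sal)), len(no3)
    )


# ---------------------------------------------------------------------------
# GeoJSON export


def write_sites_geojson(sites: Iterable[CoreSite], path: str | Path) -> None:
    """Export sites as GeoJSON points (planar coordinates, no CRS)."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.x, s.y]},
            "properties": {
                "site_id": s.site_id,
                "role": s.role,
                "collection_year": s.collection_year,
            },
        }
        for s in sites
    ]
    obj = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1), encoding="utf-8")
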