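"""Domain types, tabular I/O and validation for haul and length records.

The unit of all spatial/effort computation is a commercial trawl event
(:class:`HaulRecord`); the unit of population-structure computation is a
single measured body length (:class:`LengthSample`).  In-memory, collections
of either are plain :class:`pandas.DataFrame` objects with the canonical
columns listed in :data:`HAUL_COLUMNS` / :data:`LENGTH_COLUMNS`; the record
dataclasses carry the per-row invariants and are used during ingestion.

Coordinates are stored as signed decimal degrees (south and west negative);
any "62.5° S"-style formatting is presentation only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

HAUL_COLUMNS = [
    "haul_id",
    "vessel",
    "year",
    "month",
    "duration_h",
    "latitude_deg",
    "longitude_deg",
    "catch_t",
    "speed_mps",
    "net_width_m",
    "cluster_depth_m",
    "cluster_temp_c",
]

LENGTH_COLUMNS = ["haul_id", "length_mm"]

#: unit conversion factors into the canonical unit of each field
_UNIT_FACTORS = {
    "duration_h": {"h": 1.0, "hour": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0},
    "catch_t": {"t": 1.0, "tonne": 1.0, "kg": 1e-3},
    "speed_mps": {"m/s": 1.0, "mps": 1.0, "knot": 0.514444, "kn": 0.514444},
    "net_width_m": {"m": 1.0},
    "cluster_depth_m": {"m": 1.0},
}


class ColumnError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass(frozen=True)
class Issue:
    """One validation problem tied to a record."""

    record_id: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.record_id}: {self.rule}"


@dataclass
class Dialect:
    """Column-name mapping and unit declarations for tabular ingestion.

    ``columns`` maps canonical field names to the header names used in the
    file; absent keys mean the file already uses the canonical name.
    ``units`` maps canonical field names to the unit the file records them
    in (e.g. ``{"duration_h": "min"}``); values are converted on ingest and
    the conversion is recorded in the provenance mapping returned alongside
    the data.
    """

    columns: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(columns=raw.get("columns", {}), units=raw.get("units", {}))

    def factor(self, field_name: str) -> float:
        unit = self.units.get(field_name)
        if unit is None:
            return 1.0
        try:
            return _UNIT_FACTORS[field_name][unit]
        except KeyError as exc:
            raise ValueError(
                f"unsupported unit {unit!r} for field {field_name!r}"
            ) from exc


@dataclass
class HaulRecord:
    """One commercial trawl event with geometry, effort, catch and the
    depth/temperature of the krill swarm layer it fished."""

    haul_id: object
    vessel: str
    year: int
    month: int
    duration_h: float
    latitude_deg: float
    longitude_deg: float
    catch_t: float
    speed_mps: float
    net_width_m: float
    cluster_depth_m: float
    cluster_temp_c: float

    def violations(self) -> list[str]:
        """Return the list of invariant violations (empty if valid)."""
        out = []
        if not (-90.0 <= self.latitude_deg < 0.0):
            out.append("latitude_deg outside [-90, 0)")
        if not (-180.0 <= self.longitude_deg <= 180.0):
            out.append("longitude_deg outside [-180, 180]")
        if not (1 <= self.month <= 12):
            out.append("month outside 1..12")
        if not self.catch_t >= 0:
            out.append("catch_t negative")
        if not self.duration_h > 0:
            out.append("duration_h not positive")
        if not self.speed_mps > 0:
            out.append("speed_mps not positive")
        if not self.net_width_m > 0:
            out.append("net_width_m not positive")
        if not self.cluster_depth_m > 0:
            out.append("cluster_depth_m not positive")
        return out


@dataclass
class LengthSample:
    """One measured individual total length tied to a haul."""

    haul_id: object
    length_mm: float

    def violations(self) -> list[str]:
        if not (0.0 < self.length_mm < 120.0):
            return ["length_mm outside (0, 120)"]
        return []


@dataclass
class ValidationReport:
    """Sample-size accounting across a haul + length dataset."""

    n_hauls: int
    n_measured_hauls: int
    n_lengths: int
    per_year_counts: pd.DataFrame  # columns: year, hauls, lengths
    issues: list[Issue] = field(default_factory=list)


def quantize_length(length_mm: np.ndarray | float) -> np.ndarray | float:
    """Quantize lengths to the 0.1 mm recording precision."""
    return np.round(np.asarray(length_mm, dtype=float) * 10.0) / 10.0


def read_hauls(
    path: str | Path,
    dialect: Dialect | Mapping | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, list[Issue]]:
    """Read a haul CSV into the canonical haul table.

    Every row either becomes a valid record or contributes an
    :class:`Issue`; invalid rows are dropped in lenient mode (the default,
    commercial logbooks are dirty) and raise in ``strict`` mode.  Returns
    ``(hauls, issues)`` with row order preserved.  The returned frame
    carries a ``provenance`` entry in ``frame.attrs`` recording applied
    unit conversions.
    """
    if dialect is None:
        dialect = Dialect()
    elif isinstance(dialect, Mapping):
        dialect = Dialect(
            columns=dict(dialect.get("columns", {})),
            units=dict(dialect.get("units", {})),
        )

    raw = pd.read_csv(path)
    rename = {src: canon for canon, src in dialect.columns.items()}
    raw = raw.rename(columns=rename)

    missing = [c for c in HAUL_COLUMNS if c not in raw.columns]
    if missing:
        raise ColumnError(f"missing mandatory column(s): {', '.join(missing)}")

    issues: list[Issue] = []
    conversions: dict[str, float] = {}
    numeric = [c for c in HAUL_COLUMNS if c not in ("haul_id", "vessel")]
    df = raw[HAUL_COLUMNS].copy()
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        fac = dialect.factor(col) if col in _UNIT_FACTORS else 1.0
        if fac != 1.0:
            df[col] = df[col] * fac
            conversions[col] = fac

    bad_numeric = df[numeric].isna().any(axis=1)
    for rid in df.loc[bad_numeric, "haul_id"]:
        issues.append(Issue(rid, "unparseable or missing numeric field"))
    if strict and bad_numeric.any():
        raise ValueError(
            f"unparseable numeric values in {int(bad_numeric.sum())} row(s)"
        )
    df = df.loc[~bad_numeric]

    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        rec = HaulRecord(*row)
        viol = rec.violations()
        if viol:
            keep[i] = False
            for v in viol:
                issues.append(Issue(rec.haul_id, v))
    if strict and not keep.all():
        raise ValueError(f"{int((~keep).sum())} row(s) violate haul invariants")
    df = df.loc[keep].reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    df.attrs["provenance"] = {"source": str(path), "unit_conversions": conversions}
    if issues:
        logger.warning("read_hauls: %d issue(s) while reading %s", len(issues), path)
    return df, issues


def read_lengths(path: str | Path, strict: bool = False) -> tuple[pd.DataFrame, list[Issue]]:
    """Read a length CSV; lengths are quantized to 0.1 mm on ingest.

    Non-positive lengths become issues (dropped when lenient).  Orphan
    haul ids are *not* detectable here (no haul table in scope) — use
    :func:`summarize_inventory` for cross-table checks.
    """
    raw = pd.read_csv(path)
    if "haul_id" not in raw.columns:
        raise ColumnError("missing mandatory column(s): haul_id")
    if "length_mm" not in raw.columns:
        raise ColumnError("missing mandatory column(s): length_mm")
    df = raw[LENGTH_COLUMNS].copy()
    df["length_mm"] = pd.to_numeric(df["length_mm"], errors="coerce")

    issues: list[Issue] = []
    bad = df["length_mm"].isna() | (df["length_mm"] <= 0) | (df["length_mm"] >= 120)
    for rid in df.loc[bad, "haul_id"]:
        issues.append(Issue(rid, "length_mm not in (0, 120)"))
    if strict and bad.any():
        raise ValueError(f"{int(bad.sum())} invalid length row(s)")
    df = df.loc[~bad].reset_index(drop=True)
    df["length_mm"] = quantize_length(df["length_mm"].to_numpy())
    if len(df) == 0:
        warnings.warn(f"no length samples read from {path}", stacklevel=2)
    return df, issues


def write_hauls(hauls: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical haul table to CSV (round-trip lossless via repr)."""
    hauls.to_csv(path, index=False, columns=HAUL_COLUMNS, float_format="%.17g")


def write_lengths(lengths: pd.DataFrame, path: str | Path) -> None:
    lengths.to_csv(path, index=False, columns=LENGTH_COLUMNS, float_format="%.1f")


def summarize_inventory(
    hauls: pd.DataFrame, lengths: pd.DataFrame, issues: Iterable[Issue] = ()
) -> ValidationReport:
    """Sample-size accounting: total hauls, measured hauls (hauls with at
    least one length), total lengths, and the per-year breakdown."""
    orphan = set(lengths["haul_id"]) - set(hauls["haul_id"])
    issue_list = list(issues)
    for rid in sorted(orphan, key=str):
        issue_list.append(Issue(rid, "length sample references unknown haul"))

    year_of = hauls.set_index("haul_id")["year"]
    l_year = lengths["haul_id"].map(year_of)
    per_year = (
        pd.DataFrame(
            {
                "hauls": hauls.groupby("year").size(),
                "lengths": l_year.value_counts().astype("int64"),
            }
        )
        .fillna(0)
        .astype(int)
        .rename_axis("year")
        .reset_index()
        .sort_values("year", ignore_index=True)
    )
    measured = lengths.loc[lengths["haul_id"].isin(year_of.index), "haul_id"].nunique()
    return ValidationReport(
        n_hauls=len(hauls),
        n_measured_hauls=int(measured),
        n_lengths=int(per_year["lengths"].sum()),
        per_year_counts=per_year,
        issues=issue_list,
    )


def haul_mean_lengths(hauls: pd.DataFrame, lengths: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean body length per haul.

    Returns a table ``(haul_id, mean_length_mm, n_measured)`` covering the
    hauls that have at least one length sample; hauls without lengths are
    excluded (their count is available from :func:`summarize_inventory`).
    """
    known = lengths[lengths["haul_id"].isin(hauls["haul_id"])]
    out = (
        known.groupby("haul_id")["length_mm"]
        .agg(mean_length_mm="mean", n_measured="size")
        .reset_index()
    )
    return out
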