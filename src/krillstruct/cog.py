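"""Catch-weighted gravity center of the fishing grounds and its trajectory.

The gravity center of a period is the catch-weighted mean position of its
hauls,

    lat_w = sum(C_i * lat_i) / sum(C_i),    lon_w analogous,

a planar weighted mean on signed decimal degrees.  At 61–64° S over at
most ~12° of longitude the difference from a true spherical centroid is
negligible and the planar form matches the standard fishing-ground
centroid definition exactly.  The field names lat_w/lon_w are deliberate:
in the centroid literature X is latitude and Y longitude, an axis-swap
trap this module avoids by never using X/Y names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # WGS-84 mean radius


@dataclass(frozen=True)
class CogPoint:
    """Catch-weighted centroid of a haul subset for one period."""

    period: object
    lat_w: float
    lon_w: float
    total_catch_t: float
    n_hauls: int


def gravity_center(hauls: pd.DataFrame, period: object = None) -> CogPoint:
    """Catch-weighted mean position of a non-empty haul subset.

    Invariant under uniform rescaling of all catches; undefined (raises)
    when the total catch is zero.
    """
    if len(hauls) == 0:
        raise ValueError("gravity_center of an empty haul set")
    c = hauls["catch_t"].to_numpy(dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("undefined centroid: all catches zero")
    lat = float(np.dot(c, hauls["latitude_deg"].to_numpy(dtype=float)) / total)
    lon = float(np.dot(c, hauls["longitude_deg"].to_numpy(dtype=float)) / total)
    return CogPoint(period, lat, lon, float(total), int(len(hauls)))


def cog_trajectory(hauls: pd.DataFrame, period: str = "year") -> pd.DataFrame:
    """One gravity center per period with positive catch, in
    chronological order.  ``period`` is ``"year"`` or ``"year_month"``;
    zero-catch periods are omitted and logged."""
    if period == "year":
        keys = [hauls["year"]]
    elif period == "year_month":
        keys = [hauls["year"], hauls["month"]]
    else:
        raise ValueError("period must be 'year' or 'year_month'")

    rows = []
    for key, grp in hauls.groupby(keys if len(keys) > 1 else keys[0], sort=True):
        label = key if not isinstance(key, tuple) else key
        if grp["catch_t"].sum() <= 0:
            logger.info("cog_trajectory: period %s has zero catch, omitted", label)
            continue
        p = gravity_center(grp, period=label)
        row = {
            "period": label if not isinstance(label, tuple) else f"{label[0]}-{label[1]:02d}",
            "lat_w": p.lat_w,
            "lon_w": p.lon_w,
            "total_catch_t": p.total_catch_t,
            "n_hauls": p.n_hauls,
        }
        if isinstance(label, tuple):
            row["year"], row["month"] = label
        else:
            row["year"] = label
        rows.append(row)
    return pd.DataFrame(rows)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on the WGS-84 mean-radius sphere (6371.0088 km)."""
    p1, p2, dl = map(np.radians, (lat1, lat2, lon2 - lon1))
    dphi = p2 - p1
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def displacement(cog_a: CogPoint, cog_b: CogPoint) -> tuple[float, float, float]:
    """(Δlat deg, Δlon deg, great-circle km) from ``cog_a`` to ``cog_b``."""
    dlat = cog_b.lat_w - cog_a.lat_w
    dlon = cog_b.lon_w - cog_a.lon_w
    km = haversine_km(cog_a.lat_w, cog_a.lon_w, cog_b.lat_w, cog_b.lon_w)
    return dlat, dlon, km


def latitude_trend(trajectory: pd.DataFrame) -> float:
    """Least-squares slope of annual centroid latitude against year
    (degrees per year); negative means a southward-drifting fishery."""
    if len(trajectory) < 2:
        raise ValueError("need at least two periods for a trend")
    return float(np.polyfit(trajectory["year"], trajectory["lat_w"], 1)[0])
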