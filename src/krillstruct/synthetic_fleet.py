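"""Synthetic commercial-fleet generator.

The undeposited fishery data are stood in for by a generator that
reproduces the *statistical design* of the six-season Bransfield Strait /
South Shetland Islands krill fishery: per-year haul counts and fishing
months, a 2020 gap, ~60.5–64.5° S x 51–63° W operating box with a slow
southward drift of effort, lognormal catches, and a known
covariate -> body-length structure so every downstream estimator can be
checked for parameter recovery.

Per-haul expected mean length (mm) is

    mu = b0 + f_year(year) + f_lat(lat) + f_lon(lon)
         + b_depth * (depth - depth_ref) + f_temp(temp) + f_density(D)
         + haul effect ~ N(0, sigma_haul^2)

with  f_year   a U-shaped parabola (decline then recovery, minimum near
              the middle seasons),
      f_lat    linear in signed latitude (krill smaller toward the south),
      f_lon    a gentle dome peaked inside the box,
      f_temp   saturating rise (increase below ~0 °C then plateau),
      f_density a rise-then-slow-decay curve with mode 0.2 kg m^-2
              (gamma-shaped, rising limb steeper than the decay).

Density D feeds back through the *pipeline's own* swept-density formula
(as-printed mode) applied to the haul's generated catch and geometry, so
the density -> length loop exercises the same code path the analysis
uses.  Individual lengths are drawn Normal(mu, sigma_within) truncated to
(10, 70) mm and quantized to 0.1 mm.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import indices as _indices
from .core_data import HAUL_COLUMNS, quantize_length

_TABLE1_HAULS = {2016: 1084, 2017: 517, 2018: 704, 2019: 857, 2021: 763, 2022: 566}
_TABLE1_LENGTHS = {2016: 46200, 2017: 19600, 2018: 26800, 2019: 21000, 2021: 25600, 2022: 23000}
_TABLE1_MONTHS = {2016: (2, 5), 2017: (3, 6), 2018: (2, 5), 2019: (3, 7), 2021: (3, 6), 2022: (3, 6)}
_TABLE1_VESSELS = {2016: "Furonghai", 2017: "Longteng", 2018: "Longteng",
                   2019: "Longteng", 2021: "Furonghai", 2022: "Longfa"}


@dataclass
class LengthModel:
    """Coefficients of the generating mean-length surface (units: mm,
    per-unit-covariate where a slope)."""

    beta0: float = 40.0
    year_quad: float = 0.25          # mm / yr^2, U-shape curvature
    year_center: float = 2018.5      # season of minimum length
    lat_slope: float = 1.2           # mm / deg (signed lat: smaller south)
    lat_ref: float = -62.5
    lon_quad: float = -0.025         # mm / deg^2, dome
    lon_mode: float = -58.0
    depth_slope: float = 0.012       # mm / m
    depth_ref: float = 200.0
    temp_amp: float = 1.2            # mm, saturating rise amplitude
    temp_knee: float = -1.25         # deg C
    temp_scale: float = 0.75         # deg C
    density_amp: float = 2.0         # mm at the density mode
    density_mode: float = 0.2        # kg m^-2 (as-printed scale)
    sigma_haul: float = 1.5          # mm, unexplained between-haul SD
    sigma_within: float = 6.0        # mm, within-haul individual SD

    def mu(self, year, lat, lon, depth, temp, density) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        d = np.asarray(density, dtype=float)
        ratio = np.where(d > 0, d / self.density_mode, 0.0)
        f_den = self.density_amp * ratio * np.exp(1.0 - ratio)
        return (
            self.beta0
            + self.year_quad * (year - self.year_center) ** 2
            + self.lat_slope * (np.asarray(lat) - self.lat_ref)
            + self.lon_quad * (np.asarray(lon) - self.lon_mode) ** 2
            + self.depth_slope * (np.asarray(depth) - self.depth_ref)
            + self.temp_amp * np.tanh((np.asarray(temp) - self.temp_knee) / self.temp_scale)
            + f_den
        )


@dataclass
class FleetScenario:
    """Full specification of one synthetic fleet."""

    years: list[int] = field(default_factory=lambda: sorted(_TABLE1_HAULS))
    months_by_year: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(_TABLE1_MONTHS))
    n_hauls_by_year: dict[int, int] = field(default_factory=lambda: dict(_TABLE1_HAULS))
    n_measured_by_year: dict[int, int] = field(
        default_factory=lambda: {y: c // 200 for y, c in _TABLE1_LENGTHS.items()})
    lengths_per_haul: int = 200
    vessel_by_year: dict[int, str] = field(default_factory=lambda: dict(_TABLE1_VESSELS))
    bbox: tuple[float, float, float, float] = (-64.5, -60.5, -63.0, -51.0)
    effort_drift_deg_per_yr: float = 0.15   # southward latitude drift
    lat_center0: float = -62.0              # effort center in the first year
    lat_sd: float = 0.8
    lon_center: float = -57.0
    lon_sd: float = 2.5
    catch_lognormal: tuple[float, float] = (1.946, 0.8)   # meanlog, sdlog (t)
    duration_h_range: tuple[float, float] = (1.5, 5.0)
    speed_mps_range: tuple[float, float] = (1.3, 2.1)
    net_width_m_range: tuple[float, float] = (80.0, 120.0)
    depth_range_m: tuple[float, float] = (50.0, 350.0)
    temp_range_c: tuple[float, float] = (-2.5, 1.5)
    density_mode_name: str = "as_printed"
    length_model: LengthModel = field(default_factory=LengthModel)
    seed: int = 0

    def validate(self) -> None:
        if not self.years:
            raise ValueError("empty year list")
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if lat_min >= lat_max or lon_min >= lon_max:
            raise ValueError("degenerate bounding box")
        for name, rng in (
            ("duration_h_range", self.duration_h_range),
            ("speed_mps_range", self.speed_mps_range),
            ("net_width_m_range", self.net_width_m_range),
            ("depth_range_m", self.depth_range_m),
            ("temp_range_c", self.temp_range_c),
        ):
            if rng[0] >= rng[1]:
                raise ValueError(f"degenerate range: {name}")
        if any(self.n_hauls_by_year.get(y, 0) <= 0 for y in self.years):
            raise ValueError("n_hauls_by_year must be positive for every year")
        if self.length_model.sigma_within <= 0:
            raise ValueError("sigma_within must be positive")

    def scaled(self, fraction: float) -> "FleetScenario":
        """Down-scaled copy (haul and measured-haul counts multiplied by
        ``fraction``, at least 2 hauls / 1 measured haul per year) for
        quick experiments."""
        return replace(
            self,
            n_hauls_by_year={y: max(2, int(round(c * fraction)))
                             for y, c in self.n_hauls_by_year.items()},
            n_measured_by_year={y: max(1, min(int(round(c * fraction)),
                                              max(2, int(round(self.n_hauls_by_year[y] * fraction)))))
                                for y, c in self.n_measured_by_year.items()},
        )

    # --- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FleetScenario":
        d = dict(d)
        if "length_model" in d and isinstance(d["length_model"], dict):
            d["length_model"] = LengthModel(**d["length_model"])
        for key in ("months_by_year", "n_hauls_by_year", "n_measured_by_year", "vessel_by_year"):
            if key in d:
                d[key] = {int(y): (tuple(v) if isinstance(v, (list, tuple)) else v)
                          for y, v in d[key].items()}
        for key in ("bbox", "catch_lognormal", "duration_h_range", "speed_mps_range",
                    "net_width_m_range", "depth_range_m", "temp_range_c"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FleetScenario":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_paper_like_scenario(seed: int = 0) -> FleetScenario:
    """The reference six-season design: 4491 hauls split across
    2016–2019 and 2021–2022 (no 2020 season), 811 measured hauls with 200
    lengths each (162,200 individuals), fishing months per season, and
    the qualitative covariate -> length structure described in the module
    docstring."""
    return FleetScenario(seed=seed)


def _truncnorm(rng, lo, hi, loc, scale, size):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_fleet(scenario: FleetScenario):
    """Generate ``(hauls, lengths, truth)`` for a scenario.

    Fully reproducible given ``scenario.seed``.  ``truth`` records the
    scenario, the generating coefficients, and every measured haul's true
    expected mean length.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    lm = scenario.length_model
    lat_min, lat_max, lon_min, lon_max = scenario.bbox
    y0 = min(scenario.years)

    haul_frames = []
    for year in scenario.years:
        n = scenario.n_hauls_by_year[year]
        m_lo, m_hi = scenario.months_by_year.get(year, (1, 12))
        lat_c = np.clip(
            scenario.lat_center0 - scenario.effort_drift_deg_per_yr * (year - y0),
            lat_min + 0.2, lat_max - 0.2,
        )
        lat = _truncnorm(rng, lat_min, lat_max, lat_c, scenario.lat_sd, n)
        lon = _truncnorm(rng, lon_min, lon_max, scenario.lon_center, scenario.lon_sd, n)
        haul_frames.append(pd.DataFrame({
            "haul_id": [f"{year}-{i:05d}" for i in range(n)],
            "vessel": scenario.vessel_by_year.get(year, "SIM"),
            "year": year,
            "month": rng.integers(m_lo, m_hi + 1, size=n),
            "duration_h": rng.uniform(*scenario.duration_h_range, size=n),
            "latitude_deg": lat,
            "longitude_deg": lon,
            "catch_t": rng.lognormal(*scenario.catch_lognormal, size=n),
            "speed_mps": rng.uniform(*scenario.speed_mps_range, size=n),
            "net_width_m": rng.uniform(*scenario.net_width_m_range, size=n),
            "cluster_depth_m": rng.uniform(*scenario.depth_range_m, size=n),
            "cluster_temp_c": rng.uniform(*scenario.temp_range_c, size=n),
        }))
    hauls = pd.concat(haul_frames, ignore_index=True)[HAUL_COLUMNS]

    # density feedback through the pipeline's own swept-density formula
    density = _indices.swept_density(
        hauls["catch_t"], hauls["duration_h"], hauls["speed_mps"],
        hauls["net_width_m"], mode=scenario.density_mode_name,
    )
    mu = lm.mu(hauls["year"], hauls["latitude_deg"], hauls["longitude_deg"],
               hauls["cluster_depth_m"], hauls["cluster_temp_c"], density)
    mu = np.asarray(mu) + rng.normal(0.0, lm.sigma_haul, size=len(hauls))

    # measured-haul subset, stratified by year as in the sampling design
    measured_idx = []
    for year in scenario.years:
        pool = np.flatnonzero(hauls["year"].to_numpy() == year)
        m = min(scenario.n_measured_by_year.get(year, 0), len(pool))
        measured_idx.append(rng.choice(pool, size=m, replace=False))
    measured_idx = np.sort(np.concatenate(measured_idx))

    npl = scenario.lengths_per_haul
    mu_meas = mu[measured_idx]
    draws = _truncnorm(
        rng, 10.0, 70.0,
        loc=np.repeat(mu_meas, npl), scale=lm.sigma_within,
        size=len(measured_idx) * npl,
    )
    lengths = pd.DataFrame({
        "haul_id": np.repeat(hauls["haul_id"].to_numpy()[measured_idx], npl),
        "length_mm": quantize_length(draws),
    })

    truth = {
        "scenario": scenario.to_dict(),
        "density_mode": scenario.density_mode_name,
        "mu_by_haul": dict(zip(hauls["haul_id"], np.round(mu, 6))),
        "measured_haul_ids": list(hauls["haul_id"].to_numpy()[measured_idx]),
        "effects": {
            "year": "U-shaped, minimum near year_center",
            "latitude": "increasing in signed degrees (smaller krill south)",
            "longitude": "dome peaked at lon_mode",
            "depth": "linear increasing",
            "temperature": "saturating increase",
            "density": f"rise-then-decay, mode {lm.density_mode} kg/m^2",
        },
    }
    return hauls, lengths, truth
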