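"""Age-length classification, length-frequency and annual moment summaries,
and year-wise ANOVA with Tukey HSD post hoc comparisons.

Ages follow the published Candy–Kawaguchi length-at-age partition for
Euphausia superba (Age 0: 0–25.9 mm up to Age 6+: 55–70 mm).  The printed
bins leave 0.1 mm gaps (25.9 -> 26); since lengths are 0.1 mm-quantized,
half-open intervals at the stated lower edges reproduce the printed bins
exactly: [26.0, 40.0) is "26–39.9".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class AgeClassScheme:
    """Ordered, contiguous, half-open length-interval partition mapping
    total length to an age class.  ``bins`` is a tuple of
    ``(label, lower_mm_inclusive, upper_mm_exclusive)``; the last interval
    is closed at its upper edge so the scheme covers (0, upper] exactly."""

    bins: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        lows = [b[1] for b in self.bins]
        ups = [b[2] for b in self.bins]
        if any(u <= l for l, u in zip(lows, ups)):
            raise ValueError("empty age interval")
        if any(abs(ups[i] - lows[i + 1]) > 1e-9 for i in range(len(ups) - 1)):
            raise ValueError("age intervals must be contiguous")

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bins]

    @property
    def upper_mm(self) -> float:
        return self.bins[-1][2]

    def edges(self) -> np.ndarray:
        return np.array([self.bins[0][1]] + [b[2] for b in self.bins])


#: Candy–Kawaguchi length-at-age bins for E. superba, closed-gap form.
CANDY_KAWAGUCHI = AgeClassScheme(
    bins=(
        ("Age0", 0.0, 26.0),
        ("Age1+", 26.0, 40.0),
        ("Age2+", 40.0, 48.0),
        ("Age3+", 48.0, 51.0),
        ("Age4+", 51.0, 53.0),
        ("Age5+", 53.0, 55.0),
        ("Age6+", 55.0, 70.0),
    )
)


def assign_age(
    length_mm, scheme: AgeClassScheme = CANDY_KAWAGUCHI, strict: bool = True
):
    """Map length(s) to age-class label(s).

    Intervals are half-open at the lower edge (26.0 -> Age1+); the scheme's
    upper bound is inclusive (70.0 -> Age6+).  Out-of-range lengths raise in
    strict mode and are clamped to the terminal classes otherwise.
    """
    x = np.asarray(length_mm, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    lo, hi = scheme.bins[0][1], scheme.upper_mm
    out_of_range = (x <= lo) | (x > hi)
    if strict and out_of_range.any():
        bad = x[out_of_range][0]
        raise ValueError(f"length {bad} mm outside ({lo}, {hi}]")
    edges = scheme.edges()
    idx = np.searchsorted(edges, x, side="right") - 1
    idx = np.clip(idx, 0, len(scheme.bins) - 1)
    labels = np.array(scheme.labels, dtype=object)[idx]
    return labels[0] if scalar else labels


def age_composition(
    lengths: pd.DataFrame,
    by: str = "overall",
    hauls: pd.DataFrame | None = None,
    scheme: AgeClassScheme = CANDY_KAWAGUCHI,
    cell_deg: float = 0.1,
) -> pd.DataFrame:
    """Proportion of each age class, overall or per group.

    ``by`` is ``"overall"``, ``"year"`` or ``"cell"`` (the latter two need
    ``hauls`` to resolve each sample's haul).  Proportions sum to 1 within
    each group.  Two pooled shares of management interest are appended as
    extra columns: ``juvenile_share`` (ages 1+ and 2+ combined) and
    ``share_3plus`` (ages 3+ and older).
    """
    if len(lengths) == 0:
        raise ValueError("no length samples")
    df = lengths.copy()
    df["age"] = assign_age(df["length_mm"].to_numpy(), scheme, strict=False)

    if by == "overall":
        df["_g"] = "all"
    elif by == "year":
        if hauls is None:
            raise ValueError("by='year' requires hauls")
        df["_g"] = df["haul_id"].map(hauls.set_index("haul_id")["year"])
    elif by == "cell":
        if hauls is None:
            raise ValueError("by='cell' requires hauls")
        h = hauls.set_index("haul_id")
        latb = np.round(np.floor(h["latitude_deg"] / cell_deg) * cell_deg, 10)
        lonb = np.round(np.floor(h["longitude_deg"] / cell_deg) * cell_deg, 10)
        key = latb.astype(str) + "," + lonb.astype(str)
        df["_g"] = df["haul_id"].map(key)
    else:
        raise ValueError("by must be 'overall', 'year' or 'cell'")

    counts = (
        df.groupby("_g")["age"].value_counts().unstack(fill_value=0)
        .reindex(columns=scheme.labels, fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props["juvenile_share"] = props.get("Age1+", 0.0) + props.get("Age2+", 0.0)
    older = [l for l in scheme.labels if l not in ("Age0", "Age1+", "Age2+")]
    props["share_3plus"] = props[older].sum(axis=1)
    props.index.name = "group"
    return props.reset_index()


def length_frequency(
    lengths: pd.DataFrame,
    bin_mm: float = 1.0,
    by: str = "year",
    hauls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Length-frequency histogram with half-open bins anchored at
    multiples of ``bin_mm``; counts conserve n within each group."""
    if bin_mm <= 0:
        raise ValueError("bin_mm must be positive")
    df = lengths.copy()
    if by == "year":
        if hauls is None:
            raise ValueError("by='year' requires hauls")
        df["group"] = df["haul_id"].map(hauls.set_index("haul_id")["year"])
    elif by == "overall":
        df["group"] = "all"
    else:
        raise ValueError("by must be 'year' or 'overall'")
    df["bin_low_mm"] = np.round(np.floor(df["length_mm"] / bin_mm) * bin_mm, 10)
    out = (
        df.groupby(["group", "bin_low_mm"]).size().rename("count").reset_index()
    )
    return out


def annual_summary(
    lengths: pd.DataFrame, hauls: pd.DataFrame
) -> pd.DataFrame:
    """Moment summary of individual lengths per year.

    Columns mirror the standard krill size table: n, mean, sample SD
    (n-1), median, mode (most frequent 0.1 mm-quantized value, ties to the
    smallest), min, max, linear-interpolation quartiles, adjusted
    Fisher–Pearson skewness and bias-corrected excess kurtosis.  Years
    with n < 2 are flagged (``flag='n<2'``) with SD/skew/kurt NaN; a
    zero-variance year flags skew/kurt as undefined.
    """
    year_of = hauls.set_index("haul_id")["year"]
    df = lengths.copy()
    df["year"] = df["haul_id"].map(year_of)
    df = df.dropna(subset=["year"])
    rows = []
    for year, grp in df.groupby("year"):
        x = np.sort(grp["length_mm"].to_numpy(dtype=float))
        n = len(x)
        vals, cnts = np.unique(x, return_counts=True)
        mode = float(vals[np.argmax(cnts)])  # ties -> smallest (unique is sorted)
        row = {
            "year": int(year),
            "n": n,
            "mean": float(x.mean()),
            "sd": np.nan,
            "median": float(np.median(x)),
            "mode": mode,
            "min": float(x[0]),
            "max": float(x[-1]),
            "q25": float(np.percentile(x, 25)),
            "q75": float(np.percentile(x, 75)),
            "skew": np.nan,
            "kurt": np.nan,
            "flag": "",
        }
        if n < 2:
            row["flag"] = "n<2"
        else:
            row["sd"] = float(x.std(ddof=1))
            if row["sd"] == 0.0:
                row["flag"] = "zero variance: skew/kurt undefined"
            else:
                row["skew"] = float(stats.skew(x, bias=False))
                row["kurt"] = float(stats.kurtosis(x, bias=False))  # excess
        rows.append(row)
    return pd.DataFrame(rows).sort_values("year", ignore_index=True)


def anova_tukey(
    lengths: pd.DataFrame, hauls: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way fixed-effects ANOVA of individual lengths across years,
    plus Tukey HSD pairwise comparisons.

    Pair differences follow the earlier-minus-later convention
    (diff(2016, 2017) = mean 2016 − mean 2017), with family-wise
    ``1 − alpha`` confidence intervals.  ANOVA is on individual
    measurements, not haul means.
    """
    year_of = hauls.set_index("haul_id")["year"]
    df = lengths.copy()
    df["year"] = df["haul_id"].map(year_of)
    df = df.dropna(subset=["year"])
    df["year"] = df["year"].astype(int)
    groups = [g["length_mm"].to_numpy() for _, g in df.groupby("year")]
    years = sorted(df["year"].unique())
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two year groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each year group needs n >= 2")

    f_stat, p = stats.f_oneway(*groups)
    n = len(df)
    k = len(groups)
    anova = pd.DataFrame(
        {
            "source": ["year", "residual"],
            "df": [k - 1, n - k],
            "F": [float(f_stat), np.nan],
            "p": [float(p), np.nan],
        }
    )

    hsd = pairwise_tukeyhsd(
        df["length_mm"].to_numpy(), df["year"].to_numpy(), alpha=alpha
    )
    from itertools import combinations

    pair_idx = list(combinations(range(len(hsd.groupsunique)), 2))
    ga = [int(hsd.groupsunique[i]) for i, _ in pair_idx]
    gb = [int(hsd.groupsunique[j]) for _, j in pair_idx]
    # statsmodels reports mean(group2) - mean(group1); flip to earlier-minus-later
    pairs = pd.DataFrame(
        {
            "group_a": ga,
            "group_b": gb,
            "diff": -np.asarray(hsd.meandiffs, dtype=float),
            "lwr": -np.asarray(hsd.confint[:, 1], dtype=float),
            "upr": -np.asarray(hsd.confint[:, 0], dtype=float),
            "p_adj": np.asarray(hsd.pvalues, dtype=float),
        }
    )
    pairs = pairs.sort_values(["group_a", "group_b"], ignore_index=True)
    pairs.attrs["years"] = years
    return anova, pairs
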