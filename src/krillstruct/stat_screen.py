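"""Normality-gated correlation screening and VIF collinearity diagnostics.

The screening convention: continuous haul-level variables that pass a
normality check (mean length, density, CPUE, catch, swarm depth and
temperature) are compared with Pearson's r; ordinal/temporal/positional
variables (year, month, latitude, longitude) are compared with Spearman's
rho.  The default normality test is Lilliefors — the Kolmogorov–Smirnov
test with mean and SD estimated from the sample — because a plain K-S
test against a fully specified normal with estimated parameters is badly
anticonservative; ``test="ks"`` reproduces that naive variant when the
published routing is to be replayed literally.

No multiple-testing correction is applied across the matrix (noted in the
output metadata); significance flags are per-pair at 0.05 / 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

#: variables routed to Spearman regardless of marginal normality
DEFAULT_SPEARMAN_VARS = frozenset({"Year", "Month", "Latitude", "Longitude"})

#: the ten screening variables of the haul-level analysis
DEFAULT_SCREEN_VARS = (
    "Length",
    "Density",
    "CPUE",
    "Catch",
    "DepKRI",
    "TempKRI",
    "Year",
    "Month",
    "Latitude",
    "Longitude",
)


def normality_gate(values, alpha: float = 0.05, test: str = "lilliefors"):
    """Gate a variable on marginal normality.

    Returns ``(is_normal, statistic, p)`` with ``is_normal = (p >= alpha)``.
    ``test`` is ``"lilliefors"`` (K-S with estimated parameters, default)
    or ``"ks"`` (naive K-S against N(x̄, s), anticonservative).  Requires
    n >= 8 and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 8:
        raise ValueError(f"normality test needs n >= 8, got {len(x)}")
    if np.std(x) == 0:
        raise ValueError("zero-variance sample: normality undefined")
    if test == "lilliefors":
        stat, p = _lilliefors(x, dist="norm")
    elif test == "ks":
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError("test must be 'lilliefors' or 'ks'")
    return bool(p >= alpha), float(stat), float(p)


@dataclass
class CorrelationMatrix:
    """Mixed-method correlation matrix with per-pair significance."""

    variables: tuple[str, ...]
    coef: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame  # per-pair "pearson" / "spearman" / "undefined"
    flags: pd.DataFrame   # "" / "*" (p<0.05) / "**" (p<0.01)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (var_a, var_b, method, coef, p, flag)."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "method": self.method.loc[a, b],
                        "coef": self.coef.loc[a, b],
                        "p": self.p.loc[a, b],
                        "flag": self.flags.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def correlation_screen(
    table: pd.DataFrame,
    spearman_vars: frozenset | set | None = None,
    min_n: int = 3,
) -> CorrelationMatrix:
    """Pairwise correlation matrix with method routing.

    A pair uses Spearman if either variable is in ``spearman_vars``
    (default: year/month/latitude/longitude), else Pearson.  Missing
    values are handled by pairwise deletion; pairs with fewer than
    ``min_n`` complete rows or zero variance are flagged undefined.
    """
    if spearman_vars is None:
        spearman_vars = DEFAULT_SPEARMAN_VARS
    cols = tuple(table.columns)
    k = len(cols)
    coef = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    meth = pd.DataFrame("", index=cols, columns=cols, dtype=object)
    flg = pd.DataFrame("", index=cols, columns=cols, dtype=object)

    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = table[[a, b]].dropna()
            use_spearman = a in spearman_vars or b in spearman_vars
            name = "spearman" if use_spearman else "pearson"
            if len(sub) < min_n or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r, p, name = np.nan, np.nan, "undefined"
            elif use_spearman:
                r, p = stats.spearmanr(sub[a], sub[b])
            else:
                r, p = stats.pearsonr(sub[a], sub[b])
            coef.loc[a, b] = coef.loc[b, a] = r
            pmat.loc[a, b] = pmat.loc[b, a] = p
            meth.loc[a, b] = meth.loc[b, a] = name
            flag = "" if not np.isfinite(p) else ("**" if p < 0.01 else "*" if p < 0.05 else "")
            flg.loc[a, b] = flg.loc[b, a] = flag

    return CorrelationMatrix(
        variables=cols,
        coef=coef,
        p=pmat,
        method=meth,
        flags=flg,
        meta={"multiple_testing_correction": "none", "min_n": min_n},
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 − R²_j) from OLS of
    predictor j on all others (with intercept).

    Perfect collinearity reports +inf.  Requires at least p + 2 rows and
    no constant predictor.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictors")
    if n < p + 2:
        raise ValueError(f"VIF needs >= p+2 rows, got n={n}, p={p}")
    if np.any(X.std(axis=0) == 0):
        bad = design.columns[np.where(X.std(axis=0) == 0)[0][0]]
        raise ValueError(f"constant predictor: {bad}")
    out = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def screen_table(
    hauls_with_indices: pd.DataFrame, mean_lengths: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the ten-variable haul-level screening table from an
    indexed haul frame (see :func:`krillstruct.indices.haul_indices`) and
    per-haul mean lengths — one row per measured haul."""
    merged = hauls_with_indices.merge(mean_lengths, on="haul_id", how="inner")
    return pd.DataFrame(
        {
            "Length": merged["mean_length_mm"],
            "Density": merged["density_kgm2"],
            "CPUE": merged["cpue_tph"],
            "Catch": merged["catch_t"],
            "DepKRI": merged["cluster_depth_m"],
            "TempKRI": merged["cluster_temp_c"],
            "Year": merged["year"],
            "Month": merged["month"],
            "Latitude": merged["latitude_deg"],
            "Longitude": merged["longitude_deg"],
        }
    )
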