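"""Additive smooth model of per-haul mean body length.

The response is the natural log of the per-haul mean total length; each
predictor (year, month, longitude, latitude, swarm depth, swarm
temperature, swept density) enters through a univariate penalized cubic
B-spline smooth:

    log(L_i) = b0 + f_1(x_i1) + ... + f_m(x_im) + e_i,   e_i ~ N(0, s^2)

Each smooth uses a rank-k cubic B-spline basis (default k = 10, interior
knots at quantiles) under a sum-to-zero identifiability constraint over
the observed covariate values.  The wiggliness penalty is a quadratic
form a_j * b' S_j b per term; smoothing parameters are chosen by
generalized cross-validation by default (REML optional).  Two penalty
types are supported:

* ``"diff2"`` (default) — squared second differences of the B-spline
  coefficients.  Its null space contains the linear functions, so in the
  a -> infinity limit every smooth collapses to a straight line and the
  model reproduces ordinary multiple linear regression.
* ``"ridge"`` — shrinkage of all constrained spline coefficients.  Its
  null space is only the constant, so a -> infinity collapses the model
  to the intercept (a full-shrinkage smooth, analogous to shrinkage
  spline bases in mgcv).

Model quality is summarized by a penalized-likelihood AIC using the
effective degrees of freedom tr(H) of the smoother (a term-count AIC
cannot drive stepwise selection on penalized fits), the fraction of null
deviance explained, and adjusted R^2; per-term Wald F statistics use the
frequentist covariance of the penalized estimator with rank-rounded edf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar

from . import indices as _indices
from .core_data import haul_mean_lengths
from .stat_screen import vif as _vif

logger = logging.getLogger(__name__)

RESPONSE = "log_length"
PREDICTORS = ("Year", "Month", "Longitude", "Latitude", "DepKRI", "TempKRI", "Density")


# ---------------------------------------------------------------------------
# model frame


def build_model_frame(
    hauls: pd.DataFrame,
    lengths_or_means: pd.DataFrame,
    density_mode: str = "as_printed",
) -> pd.DataFrame:
    """Assemble the regression frame: one row per measured haul with the
    log mean length response and the seven candidate predictors.

    ``lengths_or_means`` is either a raw length table or a precomputed
    ``(haul_id, mean_length_mm, n_measured)`` table.  Density is computed
    through :func:`krillstruct.indices.swept_density` with the stamped
    mode.  Rows with any missing predictor are dropped and logged.
    """
    if "mean_length_mm" in lengths_or_means.columns:
        means = lengths_or_means
    else:
        means = haul_mean_lengths(hauls, lengths_or_means)
    h = _indices.haul_indices(hauls, mode=density_mode)
    merged = h.merge(means, on="haul_id", how="inner")
    if (merged["mean_length_mm"] <= 0).any():
        raise ValueError("non-positive mean length: log response undefined")
    frame = pd.DataFrame(
        {
            "haul_id": merged["haul_id"],
            RESPONSE: np.log(merged["mean_length_mm"].to_numpy(dtype=float)),
            "Year": merged["year"].astype(float),
            "Month": merged["month"].astype(float),
            "Longitude": merged["longitude_deg"],
            "Latitude": merged["latitude_deg"],
            "DepKRI": merged["cluster_depth_m"],
            "TempKRI": merged["cluster_temp_c"],
            "Density": merged["density_kgm2"],
        }
    )
    n0 = len(frame)
    frame = frame.dropna().reset_index(drop=True)
    if len(frame) < n0:
        logger.warning("build_model_frame: dropped %d incomplete row(s)", n0 - len(frame))
    frame.attrs["density_mode"] = density_mode
    frame.attrs["n_rows"] = len(frame)
    return frame


def vif_prescreen(
    frame: pd.DataFrame, threshold: float = 4.0, predictors=None
) -> tuple[list[str], pd.DataFrame]:
    """Exclude candidate predictors whose VIF meets the threshold.

    Returns ``(retained, report)`` where the report lists every candidate
    with its VIF and whether it was excluded.
    """
    if predictors is None:
        predictors = [c for c in PREDICTORS if c in frame.columns]
    v = _vif(frame[list(predictors)])
    report = pd.DataFrame(
        {"predictor": v.index, "vif": v.to_numpy(), "excluded": v.to_numpy() >= threshold}
    )
    retained = [p for p in predictors if v[p] < threshold]
    for p in predictors:
        if v[p] >= threshold:
            logger.info("vif_prescreen: excluding %s (VIF %.3f >= %g)", p, v[p], threshold)
    return retained, report


# ---------------------------------------------------------------------------
# spline basis machinery


class TermBasis:
    """Constrained cubic B-spline basis for one predictor.

    ``k`` basis functions with interior knots at covariate quantiles; the
    basis dimension is capped at the number of distinct values.  Columns
    are linearly transformed so the smooth sums to zero over the training
    data (identifiability next to the intercept).
    """

    def __init__(self, name: str, x: np.ndarray, k: int = 10, penalty: str = "diff2"):
        if penalty not in ("diff2", "ridge"):
            raise ValueError("penalty must be 'diff2' or 'ridge'")
        x = np.asarray(x, dtype=float)
        uniq = np.unique(x)
        k = int(min(k, len(uniq)))
        if k < 3:
            raise ValueError(f"term {name}: need >= 3 distinct values, got {len(uniq)}")
        degree = 3 if k >= 4 else k - 1
        n_interior = k - degree - 1
        lo, hi = uniq[0], uniq[-1]
        if n_interior > 0:
            qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
            qs = np.unique(qs[(qs > lo) & (qs < hi)])
        else:
            qs = np.array([])
        t = np.concatenate([[lo] * (degree + 1), qs, [hi] * (degree + 1)])
        self.name = name
        self.degree = degree
        self.knots = t
        self.k = len(t) - degree - 1  # actual basis dimension
        self.xmin, self.xmax = lo, hi

        B = self._raw(x)
        # sum-to-zero constraint: columns of Z span the null space of colmeans
        c = B.mean(axis=0)
        _, _, Vt = np.linalg.svd(c[None, :])
        Z = Vt[1:, :].T  # k x (k-1)

        if penalty == "diff2" and self.k >= 3:
            # second *divided* differences at the Greville abscissae, so the
            # penalty null space is exactly the linear functions of x even
            # with non-uniform (quantile) knots
            grev = np.array([t[i + 1:i + degree + 1].mean() for i in range(self.k)])
            D = np.zeros((self.k - 2, self.k))
            for i in range(self.k - 2):
                h1 = grev[i + 1] - grev[i]
                h2 = grev[i + 2] - grev[i + 1]
                D[i, i] = 1.0 / h1
                D[i, i + 1] = -(1.0 / h1 + 1.0 / h2)
                D[i, i + 2] = 1.0 / h2
            S = Z.T @ (D.T @ D) @ Z
        else:  # ridge: shrink every constrained coefficient
            S = np.eye(self.k - 1)

        # reparametrize so the penalty is diagonal: numerically exact
        # behaviour in both the alpha -> 0 and alpha -> infinity limits
        w, U = np.linalg.eigh(S)
        w = np.clip(w, 0.0, None)
        w[w < w.max() * 1e-12] = 0.0
        self.transform = Z @ U          # k x (k-1), raw coefs -> features
        self.pen_diag = w               # per-feature penalty weights
        self.X = B @ self.transform
        self.penalty = penalty
        self.S_rank = int((w > 0).sum())

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.xmin, self.xmax)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Constrained basis at new points (clamped to the data range)."""
        return self._raw(x) @ self.transform


class AdditiveDesign:
    """Full design for a set of smooth terms, with cached cross-products
    so repeated fits over term subsets and smoothing parameters (forward
    selection, GCV search) cost one small linear solve each."""

    def __init__(self, frame: pd.DataFrame, terms, k: int = 10, penalty: str = "diff2",
                 response: str = RESPONSE):
        self.terms = list(terms)
        self.y = frame[response].to_numpy(dtype=float)
        self.n = len(self.y)
        self.bases = {t: TermBasis(t, frame[t].to_numpy(), k=k, penalty=penalty) for t in self.terms}
        blocks = [np.ones((self.n, 1))] + [self.bases[t].X for t in self.terms]
        self.X = np.hstack(blocks)
        self.slices: dict[str, slice] = {}
        pos = 1
        for t in self.terms:
            w = self.bases[t].X.shape[1]
            self.slices[t] = slice(pos, pos + w)
            pos += w
        self.p = pos
        self.G = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.tss = float(((self.y - self.y.mean()) ** 2).sum())

    def penalty_diag(self, alphas: dict[str, float]) -> np.ndarray:
        d = np.zeros(self.p)
        for t in self.terms:
            d[self.slices[t]] = alphas[t] * self.bases[t].pen_diag
        return d


@dataclass
class GamFit:
    """A fitted additive smooth model."""

    terms: list[str]
    design: AdditiveDesign = field(repr=False)
    beta: np.ndarray = field(repr=False)
    alphas: dict[str, float] = field(default_factory=dict)
    edf_by_term: dict[str, float] = field(default_factory=dict)
    edf_total: float = 0.0
    rss: float = 0.0
    scale: float = 0.0
    aic: float = 0.0
    deviance_explained: float = 0.0
    r2_adj: float = 0.0
    gcv: float = 0.0
    Vb: np.ndarray = field(default=None, repr=False)
    fitted: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)
    term_table: pd.DataFrame = field(default=None, repr=False)
    penalty: str = "diff2"
    smoothing_method: str = "gcv"

    @property
    def formula(self) -> str:
        rhs = " + ".join(f"s({t})" for t in self.terms) or "1"
        return f"{RESPONSE} ~ {rhs}"


class _PenalizedSolve:
    """Jacobi-scaled Cholesky factorization of A = X'X + diag(penalty).

    Symmetric diagonal scaling keeps the factorization accurate for any
    smoothing parameter, including the alpha -> infinity limits, because
    the scaled matrix stays well conditioned as penalized coordinates
    decouple."""

    def __init__(self, design: AdditiveDesign, alphas: dict[str, float]):
        A = design.G + np.diag(design.penalty_diag(alphas))
        self.ds = 1.0 / np.sqrt(np.diag(A))
        At = A * self.ds[:, None] * self.ds[None, :]
        self.chol = linalg.cho_factor(At, check_finite=False)
        self.A = A

    def solve(self, b: np.ndarray) -> np.ndarray:
        if b.ndim == 1:
            return self.ds * linalg.cho_solve(self.chol, self.ds * b, check_finite=False)
        return self.ds[:, None] * linalg.cho_solve(
            self.chol, self.ds[:, None] * b, check_finite=False
        )

    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol[0])))) - 2.0 * float(
            np.sum(np.log(self.ds))
        )


def _solve_penalized(design: AdditiveDesign, alphas: dict[str, float]):
    """Return (beta, F, solver) with F = (X'X + P)^-1 X'X."""
    solver = _PenalizedSolve(design, alphas)
    beta = solver.solve(design.Xty)
    F = solver.solve(design.G)
    return beta, F, solver


def _gcv_score(design: AdditiveDesign, alphas: dict[str, float]) -> float:
    try:
        solver = _PenalizedSolve(design, alphas)
    except np.linalg.LinAlgError:
        return np.inf
    beta = solver.solve(design.Xty)
    edf = float(np.trace(solver.solve(design.G)))
    rss = design.yty - 2 * beta @ design.Xty + beta @ (design.G @ beta)
    rss = max(rss, 1e-300)
    denom = max(design.n - edf, 1e-8)
    return design.n * rss / denom**2


def _reml_score(design: AdditiveDesign, alphas: dict[str, float]) -> float:
    """Negative restricted log-likelihood with the scale profiled out
    (constants dropped); null-space dimension enters through the penalty
    ranks."""
    try:
        solver = _PenalizedSolve(design, alphas)
    except np.linalg.LinAlgError:
        return np.inf
    beta = solver.solve(design.Xty)
    pen_d = design.penalty_diag(alphas)
    rss = design.yty - 2 * beta @ design.Xty + beta @ (design.G @ beta)
    pen = float(beta @ (pen_d * beta))
    logdet_A = solver.logdet()
    logdet_S = float(np.sum(np.log(pen_d[pen_d > 0])))
    mp = design.p - sum(design.bases[t].S_rank for t in design.terms)
    return 0.5 * ((design.n - mp) * np.log(max(rss + pen, 1e-300)) + logdet_A - logdet_S)


def _optimize_alphas(design: AdditiveDesign, method: str, sweeps: int = 2,
                     log_bounds=(-5.0, 9.0)) -> dict[str, float]:
    score = _gcv_score if method == "gcv" else _reml_score
    alphas = {t: 1.0 for t in design.terms}
    for _ in range(sweeps):
        for t in design.terms:
            def f(la, term=t):
                trial = dict(alphas)
                trial[term] = 10.0**la
                return score(design, trial)

            res = minimize_scalar(f, bounds=log_bounds, method="bounded",
                                  options={"xatol": 0.05})
            alphas[t] = 10.0**res.x
    return alphas


def fit_gam(
    frame: pd.DataFrame,
    terms,
    k: int = 10,
    penalty: str = "diff2",
    alphas: dict[str, float] | float | None = None,
    method: str = "gcv",
    response: str = RESPONSE,
    design: AdditiveDesign | None = None,
) -> GamFit:
    """Fit the Gaussian additive smooth model.

    ``alphas`` fixes the smoothing parameters (a scalar applies to every
    term); otherwise they are chosen by ``method`` ("gcv" default, "reml"
    optional).  Raises on rank deficiency, naming the offending term.
    A warning is logged when rows per coefficient fall below 10.
    """
    terms = list(terms)
    if design is None:
        design = AdditiveDesign(frame, terms, k=k, penalty=penalty, response=response)
    if design.n < 10 * design.p:
        logger.warning("fit_gam: %d rows for %d coefficients (<10 per coef)",
                       design.n, design.p)
    for t in terms:
        Xt = design.bases[t].X
        if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
            raise ValueError(f"rank-deficient basis for term {t!r}")

    if alphas is None:
        alphas = _optimize_alphas(design, method)
    elif np.isscalar(alphas):
        alphas = {t: float(alphas) for t in terms}
    else:
        alphas = {t: float(alphas[t]) for t in terms}

    beta, F, solver = _solve_penalized(design, alphas)
    fitted = design.X @ beta
    resid = design.y - fitted
    rss = float(resid @ resid)
    edf_col = np.diag(F)
    edf_total = float(edf_col.sum())
    edf_by_term = {t: float(edf_col[design.slices[t]].sum()) for t in terms}
    n = design.n
    scale = rss / max(n - edf_total, 1e-8)
    dev_expl = 1.0 - rss / design.tss if design.tss > 0 else 0.0
    r2_adj = 1.0 - (rss / max(n - edf_total, 1e-8)) / (design.tss / (n - 1)) if n > 1 else np.nan
    aic = n * (np.log(2 * np.pi * max(rss, 1e-300) / n) + 1.0) + 2.0 * (edf_total + 1.0)
    gcv = n * rss / max(n - edf_total, 1e-8) ** 2

    # Bayesian covariance of the penalized estimator (the mgcv convention:
    # good across-the-function band coverage and near-nominal term tests)
    Vb = scale * solver.solve(np.eye(design.p))

    rows = []
    for t in terms:
        sl = design.slices[t]
        bj = beta[sl]
        Vj = Vb[sl, sl]
        r = max(1, int(round(edf_by_term[t])))
        w, U = np.linalg.eigh(Vj)
        order = np.argsort(w)[::-1]
        w, U = w[order[:r]], U[:, order[:r]]
        w = np.clip(w, 1e-300, None)
        stat = float(((U.T @ bj) ** 2 / w).sum())
        fval = stat / r
        pval = float(stats.f.sf(fval, r, max(n - edf_total, 1.0)))
        rows.append({"term": t, "edf": edf_by_term[t], "F": fval, "p": pval,
                     "alpha": alphas[t]})
    term_table = pd.DataFrame(rows)

    return GamFit(
        terms=terms, design=design, beta=beta, alphas=alphas,
        edf_by_term=edf_by_term, edf_total=edf_total, rss=rss, scale=scale,
        aic=float(aic), deviance_explained=float(dev_expl), r2_adj=float(r2_adj),
        gcv=float(gcv), Vb=Vb, fitted=fitted, residuals=resid,
        term_table=term_table, penalty=penalty, smoothing_method=method,
    )


def forward_select(
    frame: pd.DataFrame,
    candidates,
    criterion: str = "aic",
    k: int = 10,
    penalty: str = "diff2",
    method: str = "gcv",
    response: str = RESPONSE,
) -> tuple[pd.DataFrame, GamFit | None]:
    """Greedy forward term selection by AIC.

    At each step the candidate giving the largest AIC reduction is added;
    selection stops when no addition reduces AIC.  Returns the path table
    (step, formula, r2_adj, aic, deviance_explained_pct, term added) and
    the final fit.  The path AIC is strictly decreasing by construction.
    """
    if criterion != "aic":
        raise ValueError("only criterion='aic' is supported")
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    master = AdditiveDesign(frame, candidates, k=k, penalty=penalty, response=response)

    def subdesign(terms):
        d = AdditiveDesign.__new__(AdditiveDesign)
        d.terms = list(terms)
        d.y, d.n = master.y, master.n
        d.bases = {t: master.bases[t] for t in terms}
        cols = [0] + [j for t in terms for j in range(master.slices[t].start, master.slices[t].stop)]
        cols = np.array(cols)
        d.X = master.X[:, cols]
        d.slices = {}
        pos = 1
        for t in terms:
            w = master.bases[t].X.shape[1]
            d.slices[t] = slice(pos, pos + w)
            pos += w
        d.p = pos
        d.G = master.G[np.ix_(cols, cols)]
        d.Xty = master.Xty[cols]
        d.yty, d.tss = master.yty, master.tss
        return d

    n = master.n
    null_rss = master.tss
    current: list[str] = []
    current_aic = n * (np.log(2 * np.pi * null_rss / n) + 1.0) + 2.0 * 2.0  # intercept + scale
    path_rows = []
    best_fit = None
    remaining = list(candidates)
    step = 0
    while remaining:
        trial_fits = {}
        for t in remaining:
            d = subdesign(current + [t])
            trial_fits[t] = fit_gam(frame, current + [t], k=k, penalty=penalty,
                                    method=method, response=response, design=d)
        best_term = min(trial_fits, key=lambda t: trial_fits[t].aic)
        if trial_fits[best_term].aic >= current_aic:
            break
        step += 1
        current.append(best_term)
        remaining.remove(best_term)
        best_fit = trial_fits[best_term]
        current_aic = best_fit.aic
        path_rows.append(
            {
                "step": step,
                "added": best_term,
                "formula": best_fit.formula,
                "r2_adj": best_fit.r2_adj,
                "aic": best_fit.aic,
                "deviance_explained_pct": 100.0 * best_fit.deviance_explained,
            }
        )
    return pd.DataFrame(path_rows), best_fit


def partial_effects(fit: GamFit, term: str, grid=100) -> pd.DataFrame:
    """Centered partial-effect curve of one smooth with a ±2 SE band.

    ``grid`` is either a point count (curve over the observed covariate
    range) or an explicit array; points beyond the data range are dropped
    and flagged in ``result.attrs['truncated']``.
    """
    if term not in fit.terms:
        raise ValueError(f"term {term!r} not in fit")
    basis = fit.design.bases[term]
    if np.isscalar(grid):
        xg = np.linspace(basis.xmin, basis.xmax, int(grid))
        truncated = False
    else:
        xg = np.asarray(grid, dtype=float)
        inside = (xg >= basis.xmin) & (xg <= basis.xmax)
        truncated = bool((~inside).any())
        xg = xg[inside]
    B = basis.evaluate(xg)
    sl = fit.design.slices[term]
    f = B @ fit.beta[sl]
    Vj = fit.Vb[sl, sl]
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", B, Vj, B), 0, None))
    out = pd.DataFrame({"x": xg, "effect": f, "se": se,
                        "lower": f - 2 * se, "upper": f + 2 * se})
    out.attrs["term"] = term
    out.attrs["truncated"] = truncated
    return out


def residual_diagnostics(fit: GamFit, n_bins: int = 30) -> dict:
    """Plot-ready residual diagnostics plus a Breusch–Pagan
    heteroscedasticity test of squared residuals against fitted values."""
    r = fit.residuals
    n = len(r)
    osm, osr = stats.probplot(r, dist="norm", fit=False)
    qq = pd.DataFrame({"theoretical": osm, "sample": osr})
    rvf = pd.DataFrame({"fitted": fit.fitted, "residual": r})
    counts, edges = np.histogram(r, bins=n_bins)
    hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})

    # Breusch-Pagan: LM = n * R^2 of squared residuals on the fitted values
    z = np.column_stack([np.ones(n), fit.fitted])
    u = r**2
    coef, *_ = np.linalg.lstsq(z, u, rcond=None)
    uhat = z @ coef
    ssr = float(((u - uhat) ** 2).sum())
    tss = float(((u - u.mean()) ** 2).sum())
    lm = n * (1.0 - ssr / tss) if tss > 0 else 0.0
    bp_p = float(stats.chi2.sf(lm, df=1))

    return {
        "qq": qq,
        "residuals_vs_fitted": rvf,
        "histogram": hist,
        "bp_stat": float(lm),
        "bp_p": bp_p,
        "residual_mean": float(r.mean()),
        "edf_by_term": dict(fit.edf_by_term),
    }


def latitude_block_cv(
    frame: pd.DataFrame, terms, n_blocks: int = 5, k: int = 10,
    penalty: str = "diff2", method: str = "gcv", response: str = RESPONSE,
) -> pd.DataFrame:
    """Generic latitude-band blocked cross-validation.

    Folds are contiguous latitude bands (quantile edges), so each
    held-out block is spatially coherent.  Returns per-fold RMSE of the
    log-length prediction.  No equivalence with any specific published
    blocking scheme is claimed.
    """
    lat = frame["Latitude"].to_numpy()
    edges = np.quantile(lat, np.linspace(0, 1, n_blocks + 1))
    edges[-1] += 1e-9
    fold = np.digitize(lat, edges[1:-1])
    rows = []
    for b in range(n_blocks):
        train, test = frame[fold != b], frame[fold == b]
        if len(test) == 0 or len(train) < 50:
            continue
        f = fit_gam(train, terms, k=k, penalty=penalty, method=method, response=response)
        pred = np.full(len(test), f.beta[0])
        for t in terms:
            B = f.design.bases[t].evaluate(test[t].to_numpy())
            pred = pred + B @ f.beta[f.design.slices[t]]
        rmse = float(np.sqrt(np.mean((test[response].to_numpy() - pred) ** 2)))
        rows.append({"block": b, "n_test": len(test), "rmse": rmse,
                     "lat_low": edges[b], "lat_high": edges[b + 1]})
    return pd.DataFrame(rows)
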