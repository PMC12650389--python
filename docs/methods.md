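# Methods

This note documents the statistical models, the numerical choices, and
the design decisions behind `krillstruct`, including what the synthetic
fleet generator does and does not emulate.

## Data model

A *haul* is one commercial midwater trawl event: year, month, duration
*T* (h), position (signed decimal degrees, south and west negative),
catch *C* (t), tow speed *V* (m s⁻¹), net-mouth width *W* (m), and the
depth (m) and temperature (°C) of the targeted krill swarm layer.  A
*length sample* is one individual total length (mm, quantized to the
0.1 mm recording precision) tied to a haul.  Ingestion is lenient by
default — rows violating invariants become logged issues rather than
hard errors, because commercial logbooks are dirty — with a `strict`
switch for curated data.  Signed-degree storage keeps gridding and
centroid arithmetic unambiguous; "62.5° S"-style rendering is left to
presentation code.  One consequence worth remembering: correlations
against latitude flip sign relative to conventions that count degrees
south as positive.

## Abundance indices

CPUE is *C*/*T* in t h⁻¹.  Swept-area density divides catch by the area
swept by the net mouth.  The published formula *C*/(*V* · 60 · *T* · *W*)
multiplies a speed in m s⁻¹ by 60 although *T* is in hours, so the
implied swept distance is short by a factor of 60; the package
implements both this "as_printed" convention (the default, because it
reproduces the published magnitude scale of ~0–0.4 kg m⁻²) and a
"unit_consistent" variant with *V* · 3600 · *T*.  The two differ by
exactly 60 and the choice is stamped into every output's metadata.
Catch is converted tonnes → kg (× 1000) so the index carries kg m⁻²,
the unit on which density maps of these grounds are conventionally
scaled.

Grid cells are half-open `[edge, edge + 0.1°)` intervals anchored at
multiples of the cell size from the 0° origin, so cell membership is
independent of the data extent.  Catch is summed (conserved exactly),
CPUE and density are averaged per cell (a median switch exists; whether
published per-cell maps show means or medians is not stated), and mean
length is averaged over individuals.  No geodesic cell-area correction
is applied.

## Gravity centers

The fishing-ground centroid of a period is the catch-weighted planar
mean of haul positions on signed degrees, exactly the standard
fisheries center-of-gravity definition.  A spherical centroid was
deliberately not used: at 61–64° S across ≤ 12° of longitude the
difference is far below the positional noise of commercial logbooks,
and the planar form matches the definition as published.  Displacements
report Δlat, Δlon and the haversine distance on the WGS-84 mean radius
(6371.0088 km).  The centroid is invariant under uniform catch
rescaling and under splitting a haul into co-located parts; periods
with zero total catch have no defined centroid and are omitted with a
log entry.  Both annual and year-month weighting are supported.

## Population structure

Ages follow the published length-at-age partition for *E. superba*
(Candy–Kawaguchi growth standards).  The printed bins leave 0.1 mm gaps
("25.9" to "26"); since lengths are 0.1 mm-quantized, half-open
intervals at the stated lower edges — [26.0, 40.0) for "26–39.9" —
reproduce the printed bins exactly, with the terminal 70 mm edge
inclusive.  Annual summaries use the sample SD (n−1), linear-
interpolation quantiles, the most frequent 0.1 mm-quantized value as
the mode (ties broken to the smallest; the mode-estimation method for
continuous lengths is otherwise under-determined), adjusted
Fisher–Pearson skewness and bias-corrected *excess* kurtosis (the
convention inferred from published values clustering near zero).

The year effect is tested by one-way fixed-effects ANOVA on individual
lengths, not haul means: published Tukey interval half-widths of
~0.15 mm are only consistent with group sizes in the tens of thousands.
Tukey HSD point differences are reported as mean(earlier year) −
mean(later year) — the earlier-minus-later convention of fishery
year-contrast tables — and
equal the difference of group means exactly; the HSD machinery affects
only intervals and adjusted p-values.

## Screening statistics

The normality gate defaults to the Lilliefors test (K-S with estimated
mean/SD) because a plain K-S test against N(x̄, s) with parameters
estimated from the same sample is badly anticonservative; `test="ks"`
reproduces that naive variant for replaying published routing
decisions.  The correlation screen computes Pearson's r for pairs of
continuous haul-level variables and routes any pair involving year,
month, latitude or longitude to Spearman's ρ, with pairwise deletion
and per-pair 0.05/0.01 flags.  No multiple-testing correction is
applied across the matrix, as is conventional in fishery screening
tables; this is recorded in the output metadata.  VIFs are 1/(1−R²ⱼ) from OLS (with
intercept) of each predictor on all others; perfect collinearity
reports +∞ with a flag.

## Additive length model

The response is the natural log of per-haul mean length.  Each
predictor enters through a univariate smooth built from a rank-k cubic
B-spline basis (default k = 10; interior knots at covariate quantiles;
basis dimension capped at the number of distinct values, which matters
for Year with six seasons) under a sum-to-zero constraint over the
observed covariate values.

Two penalty types are supported, and the choice defines the model's
limiting behaviour:

- **diff2** (default): squared second *divided* differences of the
  B-spline coefficients evaluated at the Greville abscissae.  With
  quantile (non-uniform) knots, ordinary index-wise differences would
  leave a null space of functions linear in knot index rather than in
  x; divided differences make the null space exactly the linear
  functions, so α → ∞ collapses every smooth to a straight line and
  the model reproduces ordinary multiple linear regression.
- **ridge**: shrinkage of all constrained coefficients (null space =
  constant only), so α → ∞ collapses the model to the intercept —
  the analogue of shrinkage smoothers used for full term deletion.

Numerically, each term's penalty is eigen-diagonalized once and the
penalized normal equations are solved via Jacobi-scaled Cholesky; the
scaled system stays well conditioned for arbitrarily large smoothing
parameters, which is what makes the two limits above hold to ~1e-6
instead of losing accuracy with the square of the condition number.

Smoothing parameters minimize GCV, n·RSS/(n − tr H)², by cyclic 1-D
bounded searches over log₁₀α ∈ [−5, 9] (two sweeps; each evaluation is
one small Cholesky solve against cached cross-products).  A profiled
Gaussian REML criterion is available as an alternative.  Model AIC is
the penalized-likelihood form with effective degrees of freedom,
n(log 2πσ̂²ₘₗₑ + 1) + 2(tr H + 1); a term-count AIC cannot drive
stepwise selection on penalized fits.  Reported fit metrics are
deviance explained (1 − RSS/TSS for the Gaussian family) and adjusted
R².  Per-term tests are Wald F statistics using the Bayesian covariance
σ̂²(X'X + P)⁻¹ with rank set to the rounded term edf — the choice that
kept the null rejection rate near nominal in simulation, mirroring
common GAM practice.  Partial effects are the centered smooths on a
covariate grid with ±2 SE bands from the same covariance; grid points
beyond the data range are dropped and flagged rather than extrapolated.

Candidate predictors whose VIF meets the threshold (default 4) are
excluded before selection.  Forward selection greedily adds the term
with the largest AIC reduction and stops when no addition reduces AIC,
recording (formula, adjusted R², AIC, deviance explained) per step.

A latitude-band blocked cross-validation utility (quantile bands,
per-fold RMSE) is provided for spatially coherent validation; no
equivalence with any particular published blocking scheme is claimed.

## Synthetic fleet generator

The generator reproduces the *design* of the six-season fishery: the
per-year haul counts (1084/517/704/857/763/566 = 4491), fishing-month
windows, the missing 2020 season, 811 measured hauls stratified by year
(231/98/134/105/128/115) with 200 lengths each, and a
60.5–64.5° S × 51–63° W operating box whose effort center drifts south
at 0.15 deg yr⁻¹ by default.

Haul covariates are drawn independently: truncated-normal positions,
uniform months within each season's window, uniform tow duration
(1.5–5 h), speed (1.3–2.1 m s⁻¹), net width (80–120 m), swarm depth
(50–350 m) and swarm temperature (−2.5–1.5 °C); catches are lognormal
(meanlog 1.946, sdlog 0.8 — strictly positive and right-skewed, placing
the as-printed density distribution over ~0.05–0.8 kg m⁻² with its
median near 0.2).  Swept density feeds back into the length model
through the pipeline's own as-printed formula, so the density → length
loop exercises the same code path the analysis uses.

The expected mean length of a haul combines a U-shaped year effect
(quadratic, minimum mid-series), a linear signed-latitude effect
(smaller krill south), a gentle longitude dome, a linear depth effect,
a saturating temperature rise (increase below ~0 °C then plateau), and
a rise-then-slow-decay density effect with mode 0.2 kg m⁻² — the
qualitative structure the analysis is expected to recover, with effect
amplitudes of ~0.3–2 mm chosen so each is individually detectable at
the design's 811 measured hauls.  An unexplained between-haul effect
(SD 1.5 mm) keeps the model's deviance explained near 55–60% rather
than artificially high; within-haul lengths are Normal(μ, 6 mm)
truncated to (10, 70) mm — annual distributions with skew/kurtosis near
zero and SDs near 6.5 mm, matching the scale of published annual
summaries (means 38.9–44.2 mm, SD 5.5–7.5).  The 6 mm within-haul SD is
a free scenario parameter: no published within-haul variance exists to
pin it.

What the generator does **not** emulate: spatial autocorrelation of
catches and covariates (all haul covariates are independent draws),
oceanography, sea ice, predator fields, vessel targeting behaviour,
within-season growth, or measurement error beyond 0.1 mm quantization.
Passing recovery tests therefore demonstrates estimator correctness
under the design's sampling structure, not robustness to the
confounding and autocorrelation present in real fishery data.

## Determinism and provenance

Every stochastic routine takes a seed through
`numpy.random.default_rng`; the same scenario and seed give
byte-identical CSV outputs.  The pipeline bundle includes a manifest
(seed, config hash, package version, input digests, density mode) that
omits wall-clock time by default so that end-to-end byte-identity is
the default contract; a timestamp is opt-in.

## Measurement protocol for recovery checks

Recovery of the density-effect mode is measured as the argmax of the
partial-effect curve averaged over a handful of replicate fleets on a
shared grid restricted to the central 96% of observed densities: a
single fleet's argmax has a sampling SD of ~0.04 kg m⁻², and the spline
tail beyond the data support can spuriously dominate the maximum.
Selection consistency is measured over 50 replicate fleets with three
pure-noise candidates added after VIF prescreening.  Problem sizes used
throughout the tests — the full 4491-haul design for recovery checks
and a ~5% scaled design for plumbing tests — are the package's own
choices balancing statistical resolution against suite runtime.

## Known limitations

- The GAM is Gaussian-identity only (log-transformed response), with
  univariate smooths; no tensor/spatial interaction smooths and no
  residual autocorrelation structure.
- GCV optimization is cyclic 1-D rather than full Newton on the joint
  criterion; with near-orthogonal smooths (the fleet design) this
  converges in two sweeps, but strongly concurved designs may need more.
- Term p-values inherit the usual post-selection optimism of
  GCV-smoothed models; they are approximately, not exactly, calibrated.
- The Spearman/Pearson routing is a fixed variable-role convention, not
  a per-dataset re-derivation from the normality gate.
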