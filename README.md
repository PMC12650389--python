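# krillstruct

Population-structure analysis of commercial Antarctic krill (*Euphausia
superba*) trawl fisheries, built for the Bransfield Strait / South
Shetland Islands grounds (CCAMLR subarea 48.1) but applicable to any
haul-level logbook + length-measurement dataset.

Commercial krill logbooks record, per haul, the tow geometry and effort
(duration *T* in hours, tow speed *V* in m s⁻¹, net-mouth width *W* in
m), the catch *C* in tonnes, the position, and the depth/temperature of
the targeted krill swarm; a subset of hauls carries ~200 individual
total-length measurements at 0.1 mm precision.  From these the package
computes:

- **Abundance indices** — CPUE = *C*/*T* (t h⁻¹) and swept-area density
  *C*/(*V* · 60 · *T* · *W*) in kg m⁻², with both the published
  ("as-printed") and the unit-consistent (*V* · 3600 · *T*) swept-distance
  conventions, which differ by exactly 60; aggregation onto a 0.1° × 0.1°
  grid with half-open, origin-anchored cells.
- **Fishing-ground trajectory** — per-period catch-weighted gravity
  centers  lat_w = Σ Cᵢ·latᵢ / Σ Cᵢ  (lon analogous), displacement in
  degrees and great-circle km, and the latitude trend of the trajectory.
- **Population structure** — length-to-age classification on the
  published length-at-age partition for *E. superba* (Age 0: <26 mm …
  Age 6+: 55–70 mm), age composition, length-frequency distributions,
  annual moment summaries (mean, SD, quartiles, mode, skewness, excess
  kurtosis), and one-way ANOVA with Tukey HSD year contrasts.
- **Screening statistics** — Lilliefors/K-S normality gating, a mixed
  Pearson/Spearman correlation matrix (temporal/positional variables
  route to Spearman), and variance-inflation-factor collinearity
  diagnostics.
- **Additive length model** — a Gaussian GAM of log per-haul mean length,

  log(L) ~ s(Year) + s(Month) + s(Longitude) + s(Latitude) + s(DepKRI) + s(TempKRI) + s(Density) + ε,

  with penalized cubic B-spline smooths, GCV (or REML) smoothing
  selection, VIF prescreening of candidates, greedy forward selection by
  AIC, per-term edf/F/p summaries, partial-effect curves with ±2 SE
  bands, and residual/heteroscedasticity diagnostics.

Because commercial fishery data of this kind are rarely deposited, the
package ships a first-class synthetic fleet generator
(`krillstruct.synthetic_fleet`) that reproduces the six-season survey
design (4491 hauls over 2016–2022 with no 2020 season, 811 measured
hauls × 200 lengths = 162,200 individuals) and a known covariate →
length structure, so every estimator can be validated by parameter
recovery.

## Worked example

```python
from krillstruct import size_gam
from krillstruct.cog import cog_trajectory, latitude_trend
from krillstruct.synthetic_fleet import default_paper_like_scenario, generate_fleet

hauls, lengths, truth = generate_fleet(default_paper_like_scenario(seed=1))

traj = cog_trajectory(hauls, period="year")
print(round(latitude_trend(traj), 3))          # -0.138

frame = size_gam.build_model_frame(hauls, lengths)
retained, _ = size_gam.vif_prescreen(frame)    # drops nothing here: max VIF 1.3
path, fit = size_gam.forward_select(frame, retained)
print(list(path["added"]))
# ['DepKRI', 'Year', 'Latitude', 'TempKRI', 'Density', 'Longitude']
print(round(100 * fit.deviance_explained, 1))  # 60.4
```

The centroid latitude trend of −0.138 deg yr⁻¹ recovers the southward
effort drift of 0.15 deg yr⁻¹ imposed by the generator; forward AIC
selection picks exactly the six generating covariates (Month, which has
no generating effect, is never added), and the selected model explains
60.4% of the deviance in log mean length.  The `examples/` directory
contains one short script per capability, each printing the numbers it
computes and what they mean.

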