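"""Additive smooth model of log mean body length per haul.

Pipeline: assemble the model frame (log mean length vs seven
candidates), drop collinear predictors (VIF >= 4), select terms by
forward AIC over penalized cubic-spline smooths, then inspect per-term
effective degrees of freedom, F tests and partial-effect curves.
"""

import numpy as np

from krillstruct import size_gam
from krillstruct.synthetic_fleet import default_paper_like_scenario, generate_fleet

hauls, lengths, truth = generate_fleet(default_paper_like_scenario(seed=1))

frame = size_gam.build_model_frame(hauls, lengths)
retained, vif_report = size_gam.vif_prescreen(frame)
print("VIF prescreen (threshold 4):")
print(vif_report.round(3).to_string(index=False))

path, fit = size_gam.forward_select(frame, retained)
print("\nforward AIC selection path:")
print(path[["step", "added", "aic", "deviance_explained_pct"]].round(2).to_string(index=False))

print(f"\nfinal model: {fit.formula}")
print(f"deviance explained: {100 * fit.deviance_explained:.1f}%, "
      f"adjusted R^2: {fit.r2_adj:.3f}, AIC: {fit.aic:.1f}")
print("\nper-term smooth summaries:")
print(fit.term_table[["term", "edf", "F", "p"]].round(4).to_string(index=False))

lo, hi = np.quantile(frame["Density"], [0.02, 0.98])
pe = size_gam.partial_effects(fit, "Density", grid=np.linspace(lo, hi, 300))
mode = float(pe["x"][pe["effect"].idxmax()])
print(f"\nrecovered density effect peaks at {mode:.3f} kg/m^2 "
      f"(generator places the rise-then-decay mode at "
      f"{truth['scenario']['length_model']['density_mode']} kg/m^2)")

diag = size_gam.residual_diagnostics(fit)
print(f"heteroscedasticity check (Breusch-Pagan): p = {diag['bp_p']:.3f} "
      "(> 0.05 means no evidence of non-constant variance)")
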