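"""Normality-gated correlation screen of the ten haul-level variables.

Continuous variables that plausibly pass a normality check (mean length,
density, CPUE, catch, swarm depth/temperature) are compared with
Pearson's r; temporal and positional variables (year, month, latitude,
longitude) route to Spearman's rho.  Coordinates are signed degrees
(south negative), so the sign of latitude correlations is relative to
northward-increasing values.
"""

from krillstruct.core_data import haul_mean_lengths
from krillstruct.indices import haul_indices
from krillstruct.stat_screen import correlation_screen, normality_gate, screen_table
from krillstruct.synthetic_fleet import default_paper_like_scenario, generate_fleet

hauls, lengths, _ = generate_fleet(default_paper_like_scenario(seed=1))

table = screen_table(haul_indices(hauls), haul_mean_lengths(hauls, lengths))

ok, stat, p = normality_gate(table["Length"])
print(f"mean length normality (Lilliefors): stat={stat:.4f}, p={p:.3f} -> "
      f"{'treated as normal' if ok else 'not normal'}")

corr = correlation_screen(table)
print("\ncorrelations of mean length with each screening variable:")
for var in table.columns[1:]:
    print(f"  Length ~ {var:10s} {corr.method.loc['Length', var]:8s} "
          f"{corr.coef.loc['Length', var]:+.3f} {corr.flags.loc['Length', var]}")
print("\n'**' marks p < 0.01 (no multiple-testing correction across the matrix).")
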