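"""Age-length composition, annual length summaries, and year contrasts.

Lengths map onto the published length-at-age partition for E. superba
(Age 0 below 26 mm through Age 6+ at 55-70 mm); annual moment summaries
and a one-way ANOVA with Tukey HSD quantify between-season size shifts.
"""

from krillstruct.population_structure import (
    age_composition,
    annual_summary,
    anova_tukey,
    assign_age,
)
from krillstruct.synthetic_fleet import default_paper_like_scenario, generate_fleet

hauls, lengths, _ = generate_fleet(default_paper_like_scenario(seed=1).scaled(0.2))

print("a 44.8 mm krill is", assign_age(44.8), "- the 40-47.9 mm class")

props = age_composition(lengths, by="overall").iloc[0]
print("\nage composition (share of individuals):")
for label in ["Age0", "Age1+", "Age2+", "Age3+", "Age4+", "Age5+", "Age6+"]:
    print(f"  {label:6s} {100 * props[label]:5.1f}%")
print(f"  juveniles (1+ and 2+) combined: {100 * props['juvenile_share']:.1f}%")

print("\nannual summaries (mm):")
print(annual_summary(lengths, hauls)[["year", "n", "mean", "sd", "median", "skew", "kurt"]]
      .round(2).to_string(index=False))

anova, pairs = anova_tukey(lengths, hauls)
print(f"\nANOVA across years: F = {anova.loc[0, 'F']:.1f}, p = {anova.loc[0, 'p']:.2g}")
print("largest pairwise mean difference (earlier year minus later year):")
print(pairs.loc[pairs['diff'].abs().idxmax()].round(3).to_string())
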