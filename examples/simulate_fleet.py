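"""Generate a synthetic krill fleet and account for its sample sizes.

The reference design mirrors a six-season commercial fishery (2016-2022,
no 2020 season): per-year haul counts, fishing months, and a random
subset of hauls with 200 individual length measurements each.
"""

from krillstruct.core_data import summarize_inventory
from krillstruct.synthetic_fleet import default_paper_like_scenario, generate_fleet

scenario = default_paper_like_scenario(seed=1)
hauls, lengths, truth = generate_fleet(scenario)

report = summarize_inventory(hauls, lengths)
print(f"hauls: {report.n_hauls}, measured hauls: {report.n_measured_hauls}, "
      f"lengths: {report.n_lengths}")
print(report.per_year_counts.to_string(index=False))
print("\nEach measured haul contributes 200 lengths, so measured hauls x 200")
print("equals the total length count; the per-year split follows the design.")
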