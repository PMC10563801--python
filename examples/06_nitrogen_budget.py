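"""Decadal watershed nitrogen budget by source.

Applies the loading model to a synthetic watershed history (1930-2010)
and prints the per-decade totals and the dominant source.
"""

from paleoscape import default_nlm_params, nlm_budget
from paleoscape.synthetic import ScenarioConfig, gen_watershed_history

history = gen_watershed_history(ScenarioConfig(), seed=0)
budget = nlm_budget(history, default_nlm_params())

print("decade   total kg N/yr   dominant source   fertilizer share")
for decade, row in budget.table.iterrows():
    print(f"{decade}   {row['total']:13,.0f}   {budget.dominant_source(decade):15s}"
          f"   {row['frac_fertilizer']:.2f}")
print()
print("Fertilizer surplus (application minus harvest export, times a")
print("leaching fraction) overtakes livestock by mid-century and dominates")
print("every decade from 1970 on; totals plateau after 1980.")
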