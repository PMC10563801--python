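"""Decompose an annual isotope series into a step offset plus trends.

Runs the Pettitt test on a 45-point series carrying a +3 permil step at
1946 and a 0.05 permil/yr trend over 1950-1980, then splits the series
at the detected change year and fits each side by OLS.
"""

from paleoscape import decompose, dif_abs, gen_core_timeseries, gen_sites
from paleoscape.synthetic import ScenarioConfig, subsample_series

cfg = ScenarioConfig(trend_start=1950, noise_sd=0.3, ar1_coeff=0.3)
site = [s for s in gen_sites(cfg) if s.role == "focal"][0]
series, truth = gen_core_timeseries(site, cfg, seed=11)
s45 = subsample_series(series, 45)

d = decompose(s45, harbor_year=1946, harbor_tolerance=10)
print(f"Pettitt change year: {d.change_year:.0f} "
      f"(p = {d.flags['pettitt_p']:.2e})")
print(f"step offset at change year: {d.step_offset:.2f} permil "
      f"(truth {truth.step_magnitude})")
print(f"slope after change: {d.slope_after:.4f} permil/yr")
print(f"attributed to inlet construction (1946 +/- 10): "
      f"{d.flags['step_attributed_to_inlet']}")

dif, abs_v = dif_abs(s45)
print(f"DIF (2010 - 1850) = {dif:+.2f} permil, ABS (2010) = {abs_v:.2f} permil")
print(f"fraction of fitted change before 1988: {d.fraction_before_year(1988):.2f}")
print()
print("The step is read as the abrupt tidal-exchange shift from inlet")
print("construction; the post-change slope as the gradual fertilizer signal.")
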