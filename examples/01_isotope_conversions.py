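"""Isotope delta notation and molar C/N stoichiometry.

Converts abundance ratios to per-mil delta values and weight-percent
elemental contents to the molar C/N ratio used throughout the package.
"""

from paleoscape import cn_molar, delta_value, ratio_from_delta

R_STANDARD = 0.0036765  # 15N/14N of atmospheric N2

# a sample whose 15N/14N ratio sits 1.122% above the atmospheric standard
r_sample = R_STANDARD * 1.01122
d15n = delta_value(r_sample, R_STANDARD)
print(f"delta15N = {d15n:.2f} permil")
print(f"round-trip ratio = {ratio_from_delta(d15n, R_STANDARD):.10f}")

# sediment with 2.0 wt% C and 0.2 wt% N
cn = cn_molar(2.0, 0.2)
print(f"molar C/N = {cn:.2f}")
print()
print("delta = (Rsample/Rstandard - 1) x 1000; a molar C/N near 11-12 is a")
print("mixed marine/terrestrial organic-matter signature.")
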