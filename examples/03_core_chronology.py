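"""Date a sediment core: markers, CRS cross-check, Bayesian age-depth model.

Generates a radionuclide profile under constant 0.25 cm/yr accretion,
detects the 1953/1963/1974 chronomarkers, and compares the classical
constant-rate-of-supply ages with the Bayesian posterior.
"""

import numpy as np

from paleoscape import crs_ages, detect_markers, fit_age_depth
from paleoscape.chronology import MCMCConfig
from paleoscape.synthetic import ScenarioConfig, gen_radionuclide_profile

cfg = ScenarioConfig()  # accretion 0.25 cm/yr, 5% 210Pb measurement noise
profile, truth = gen_radionuclide_profile(cfg, seed=4)

for m in detect_markers(profile):
    print(f"marker {m.kind:14s} depth {m.depth:5.1f} cm -> {m.calendar_year:.0f}")

crs = crs_ages(profile, supported_level=cfg.supported_pb210)
post = fit_age_depth(profile, detect_markers(profile),
                     mcmc=MCMCConfig(iterations=3000), seed=4)

acc = post.accretion_draws
lo, hi = np.percentile(acc, [2.5, 97.5])
print(f"\nposterior accretion {acc.mean():.3f} cm/yr (95% CI {lo:.3f}-{hi:.3f}); "
      f"truth {truth['accretion_cm_yr']}")
z = 15.0
bayes_age = np.interp(z, post.depth_grid, profile.collection_year - post.mean_year)
print(f"age at {z:.0f} cm: Bayesian {bayes_age:.0f} yr, "
      f"CRS {float(crs.age_at(z)):.0f} yr, truth {z / 0.25:.0f} yr")
print()
print("The Bayesian model samples per-slab accretion increments with a")
print("gamma-autoregressive prior; every posterior draw is monotone in depth.")
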