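# Default nitrogen-loading-model coefficients.
#
# Values are literature-informed defaults from the published
# nitrogen-loading-model lineage (per-capita wastewater N, septic plume
# transmission, land-cover deposition retention, fertilizer leaching) and
# standard cattle excretion rates.  They are substitutes for any
# site-specific calibration and should be overridden per watershed.

per_capita_n: 4.8            # kg N person^-1 yr^-1 in domestic wastewater
septic_transmission: 0.35    # fraction of septic-system N reaching receiving waters
sewered_loss: 0.9            # fraction of sewered N removed (treatment + routing)
deposition_retention:        # fraction of atmospheric N retained, by land cover
  cultivated: 0.62
  natural: 0.90
  impervious: 0.15
  wetland: 0.90
fertilizer_leaching: 0.61    # fraction of net fertilizer surplus exported
livestock_excretion:         # kg N head^-1 yr^-1
  dairy_cattle: 100.0
  other_cattle: 60.0
livestock_loss:              # fraction of excreted N captured before export
  dairy_cattle: 0.8          # retention-pond capture at the remaining dairy
  other_cattle: 0.5
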