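# Methods

This note records the models implemented in `paleoscape`, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate about real sediment records.

## Domain conventions

Depths are cm below the sediment surface with half-open intervals
[top, bottom); the surface is 0 cm at the collection date. Coordinates are
planar metres; the estuary channel is abstracted to a 1-D curvilinear axis
with the mouth at coordinate 0 and the head at `channel_length` — this
reproduces head–mouth gradients without real shoreline geometry. δ values
are plain per-mil reals (standards: atmospheric N₂ for N, VPDB for C; δ = 0
by definition). Molar C/N uses fixed atomic weights C = 12.011,
N = 14.007. Missing measurements propagate as missing through binning and
mapping — nothing is imputed silently; series sent to the change-point
stage must be explicitly interpolated first (`interpolate_missing`).

## Synthetic estuary (the test bed)

The generator emulates the observables of a grid-cored estuary:

* **Sites**: a regular grid (default 200 m, 85 sites) clipped to a
  rectangular channel; ≥ 3 *focal* sites spread mouth-to-head receive 1-cm
  sectioning and radionuclide profiles, the rest 10-cm (0–50 cm) and 25-cm
  (50–100 cm) sections.
* **Spatial truth**: per era and variable, a linear mouth→head gradient
  plus a zero-mean Gaussian random field with spherical covariance, sampled
  exactly by covariance-matrix Cholesky factorization at the site locations
  (exactness at desk scale beats spectral approximations for n ≤ a few
  hundred). Off-site evaluation uses the simple-kriging conditional mean of
  the realized field, which is finite everywhere and exact at the sites.
* **Timeseries** (1850–2010, annual): baseline + step·1[year ≥ 1946] +
  slope·clamp(year − 1940, 0, 40) + AR(1) noise. Defaults: step 3‰, slope
  0.05 ‰ yr⁻¹, innovation sd 0.3‰ (the papers in this area rarely state
  isotope measurement error; 0.3‰ is a realistic long-term external
  precision and is exposed in config), AR coefficient 0.3, initialized at
  the stationary variance sd²/(1−φ²).
* **Radionuclide profiles**: constant accretion (0.25 cm yr⁻¹), constant
  ²¹⁰Pb influx, fixed dry bulk density 1.0 g cm⁻³ (no density profile is
  modeled; configurable). Slab activities are *slab-integrated* (mass-
  weighted) means — what a gamma count on a homogenized slab measures —
  so the noiseless generator output is exactly representable by the
  age-model likelihood. ¹³⁷Cs is zero below the 1953 depth with a Gaussian
  pulse at the 1963 depth; total Pb is background plus a pulse at the 1974
  depth. Measurement noise is multiplicative (5% CV default).
* **Watershed history** (decadal 1930–2010): monotone population growth;
  fertilizer application flat to 1940, rising steeply to 1980, then
  plateaued; cultivated area rising then declining after 1980; livestock
  peaking above 3300 head in 1970 and falling to ~1000 by 2010; slowly
  rising deposition. The table is deterministic given the config — the
  shapes themselves are the conditions under test.

What passing tests show: the estimators recover known parameters under
idealized noise (iid or AR(1), Gaussian, stationary fields, constant
accretion). What they do not show: robustness to bioturbation/mixing,
compaction, density gradients, non-stationary accretion, anisotropy, or
diagenetic overprinting of isotope signals — none of which the generator
simulates.

## Age–depth chronology

Three routes, deliberately redundant:

1. **Markers**: deepest ¹³⁷Cs above threshold (5% of the profile maximum)
   → 1953, placed at the slab *bottom* since it is a maximum depth; ¹³⁷Cs
   maximum → 1963 and total-Pb maximum → 1974, placed at slab midpoints
   with ties broken toward the shallower slab; surface → collection year.
   Marker sd defaults: 2 yr for chronomarkers, 0.5 yr for the surface.
   Radiocarbon dates enter as pre-calibrated calendar years with normal
   errors; calibration-curve arithmetic is out of scope.
2. **CRS** (cross-check only): ages from the cumulative excess-inventory
   ratio. A tail correction extrapolates the inventory below the deepest
   slab from an exponential fit to the deepest positive slabs; without it
   CRS ages are biased old near the profile bottom. Depths with
   non-positive inventory are flagged, never extrapolated.
3. **Bayesian model** (primary): a deliberately auditable simplification of
   the Bacon/Plum family — per-slab accretion increments αᵢ (yr cm⁻¹) with
   Gamma(shape 1.5, mean from the strongest chronomarker) priors, a
   Gaussian penalty (sd 0.35) on successive log-increments standing in for
   Bacon's memory parameter, and lognormal priors on influx and supported
   activity centred on data-driven moments (surface excess, deepest slab).
   Likelihood: normal densities of measured slab totals about the modeled
   slab-integrated activity, and of marker years about modeled ages.
   Sampling: Metropolis-within-Gibbs, 5000 iterations, 50% burn-in, thin 2,
   proposal scales adapted during burn-in toward 30% acceptance; a final
   acceptance rate outside [0.1, 0.6] sets a warning flag in the result,
   never an exception. Measured errors are floored at 0.5% of signal so a
   noiseless profile cannot make the likelihood numerically degenerate.
   Every draw is monotone because increments are positive by construction.

**Composite chronology**: per-depth mean of the per-core posterior-mean
years with equal weighting (the pooling weights are genuinely open; equal
weights are the least informative choice and are documented here), and a
95% interval from the pooled draws. If pooling breaks monotonicity the mean
is isotonically adjusted (pool-adjacent-violators); per-core means are
monotone already. The composite covers the intersection of the cores'
depth ranges and flags truncation.

**Era bins**: mapping eras are *derived* — each era is the calendar span of
one coarse depth section as dated by the composite chronology (deepest
sections merged so at most six bins remain). This mirrors how the era
labels of such studies arise: they are chronology outputs ("ca." dates),
not a priori bins. A fixed six-era set is also provided for workflows with
externally given bins.

## Isoscapes

Classical Matheron semivariogram, 12 lag bins to half the maximum pairwise
distance by default; parametric families fitted by pair-count-weighted
least squares with nugget, sill ≥ 0 and bounded range, falling back to the
moment-based initial estimate (flagged) on optimizer failure. γ(0) = 0
exactly with a nugget jump at h → 0⁺, so kriging interpolates exactly at
data points; the kriging matrix uses a zero diagonal. The exponential and
Gaussian families use the *effective-range* convention (γ reaches ~95% of
the sill at the stated range), matching common GIS defaults. "Linear with
linear/quadratic drift" is implemented as universal kriging with a linear
variogram and polynomial drift of order 1 or 2.

Duplicate coordinates are averaged before solving. A degenerate all-zero
model (constant field) short-circuits to the mean with zero variance.
Negative kriging variances from floating-point cancellation are clipped
at 0.

Family selection: a seeded random 15% of points, each predicted
leave-one-out from all remaining points under each candidate family fitted
on the retained points; the family with the smallest RMSE wins, ties
resolving by the fixed family order (spherical first). The phrase
"leave-one-out cross validation of 15% of the points" is internally
contradictory; this reading honors both halves and is reproducible by
seed. A known limitation, quantified in the acceptance run: with six
near-equivalent families (circular differs from spherical by < 3% of sill
at every lag) and ~13 hold-out residuals, selection identifies the true
family's sph/exp pair in only ~12–14 of 20 trials — kriging's robustness
to variogram family is exactly what limits the procedure's power. Maps
meant for cross-era comparison should force one family (the pipeline
forces spherical) so era differences reflect data, not interpolator
choice.

Maps: regular planar grid (50 m cells by default; 100 m in the pipeline
fixture), masked to the convex hull of contributing sites buffered by one
cell. Per-era site values are unweighted means of that site's era-assigned
samples. Eras with fewer than 4 sites are skipped.

## Change-point decomposition

Pettitt statistic computed by a vectorized double-cumulative-sum; an
O(n²)/naive double-loop implementation is kept in the package as the
oracle. The approximate significance p = 2·exp(−6K²/(n³+n²)) is known to
be conservative under mild autocorrelation; under an iid null (n = 45) the
empirical rejection rate at 0.05 stays below 0.08 (asserted in the suite).
No autocorrelation-corrected variant and no multiple change-point search
are attempted; series are tested raw (not detrended). The reported change
year is the last year of the pre-change regime (the change occurs
immediately after it), the convention of the standard R implementation.

Split regression: OLS on each side (before inclusive of the change year),
requiring ≥ 3 points per side; the step offset is the gap between the two
fits evaluated at the change year. The step is attributed to inlet
construction when the change year falls within 1946 ± 10; the trend
contribution is slope_after × (end − change year). Significance gate:
α = 0.05 (the underlying studies report p-values without stating a
threshold); insignificant series get a trend-only decomposition, flagged.
With the default generator the post-change OLS slope spans both the active
trend (to 1980) and the subsequent plateau, so it systematically reads
~0.5–0.6× the true ramp slope — it is a summary of the whole post-change
period, not an estimate of the ramp coefficient.

DIF/ABS use the nearest observed year within 5 yr of the 1850/2010
endpoints. `fraction_before_year` evaluates the fitted piecewise model,
clipped to [0, 1].

Water-quality pairing joins annual means (arithmetic mean of available
months) with same-year sediment values over 1990–2010 and reports a
Pearson correlation (≥ 3 overlapping years; constant inputs flagged).

## Nitrogen loading

A source-attribution budget, not a transport model: no in-stream or
estuarine transformation, no groundwater travel-time attenuation (the
original loading-model lineage includes one; it is omitted here and the
inputs table is the place to pre-attenuate if needed), decadal snapshots
piecewise-constant in between. Crop export is subtracted *before* the
leaching fraction (net-surplus formulation), so early decades with export
exceeding application contribute zero fertilizer load. All coefficients
live in `data/nlm_params.yaml` — literature-informed defaults
(per-capita wastewater N 4.8 kg yr⁻¹, septic transmission 0.35, sewered
loss 0.9, deposition retention 0.9 natural/wetland, 0.62 cultivated, 0.15
impervious, fertilizer leaching 0.61, excretion 100/60 kg head⁻¹ yr⁻¹ for
dairy/other cattle, dairy retention-pond capture 0.8) — and are validated
(fractions in [0, 1]) before any computation. They are substitutes for
site-specific calibration and should be overridden per watershed.

## Pipeline and reproducibility

All stochastic stages derive their seeds from one global seed; reports are
JSON with sorted keys and values rounded to fixed precision, so reruns are
byte-identical (wall-clock timings go to the log only). The pipeline
default of 2000 MCMC iterations per core (vs the standalone default of
5000) keeps the three-core fixture run near twenty seconds; posterior
summaries at the fixture's data strength are stable well below that.
Problem sizes used by the acceptance run — 200 series for the change-point
checks, 20 cores for chronology recovery, 20 field realizations for
variogram selection, 20 small instances for the kriging oracle — are the
package's chosen desk-scale study conditions.

## Known limitations

* No bioturbation/mixing, compaction, or density-profile modeling; ages
  below the ²¹⁰Pb horizon lean on the accretion prior's memory.
* No anisotropic variograms, co-kriging, or projection handling.
* The Pettitt p-value is approximate and the test is applied to raw,
  possibly autocorrelated series (flagged above).
* Variogram family selection has low power by construction (see above);
  forced-family maps are the recommended cross-era mode.
* The loading model's defaults are generic; absolute budgets are only as
  good as the coefficients supplied.
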