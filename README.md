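# paleoscape

Historical estuarine nutrient baselines from sediment cores.

Water-quality monitoring rarely reaches back more than a few decades, so the
"reference state" it offers for nutrient regulation is already a shifted
baseline. This package reconstructs multi-century nutrient history for an
estuary from a grid of sediment cores, combining four analyses that are
usually run separately:

1. **Geochronology** — per-core age–depth models from excess ²¹⁰Pb decay and
   fallout chronomarkers (deepest ¹³⁷Cs → 1953, ¹³⁷Cs maximum → 1963,
   total-Pb maximum → 1974), pooled into an estuary-wide *composite
   chronology* that dates the undated cores.
2. **Isoscapes** — era-binned kriged maps of sediment δ¹⁵N, δ¹³C and molar
   C/N across the estuary, with data-driven variogram selection.
3. **Change-point decomposition** — the Pettitt test on annual isotope
   series, splitting each record into a step offset at the detected change
   year (e.g. harbor-inlet construction, 1946 ± 10) plus pre/post linear
   trends, summarized as DIF (2010 − 1850 change) and ABS (2010 value).
4. **Nitrogen loading** — a decadal watershed budget attributing N inputs to
   fertilizer, wastewater, atmospheric deposition and livestock.

A first-class synthetic-data module generates estuaries with known ground
truth (spatial gradients, a +3‰ step at 1946, a 0.05 ‰ yr⁻¹ trend over the
fertilizer era, constant accretion with radionuclide profiles, watershed
histories), so every stage can be validated by parameter recovery.

## The statistics at the core

**Age–depth model.** For slab thicknesses Δzᵢ the calendar age at depth is
t(z) = Σ αᵢΔzᵢ with accretion increments αᵢ (yr cm⁻¹) given a gamma prior and
an autoregressive smoothness penalty on log αᵢ, plus explicit ²¹⁰Pb influx Φ
and supported activity s. The likelihood combines slab-integrated modeled
activity, Φ(e^{−λt_top} − e^{−λt_bot})/(λρΔz) + s with λ = ln2/22.3 yr⁻¹,
against the measured profile, and marker years against modeled ages. Sampling
is adaptive Metropolis-within-Gibbs; every draw is monotone by construction.
The classical CRS model, t(z) = λ⁻¹ ln[I(0)/I(z)] with I(z) the cumulative
excess-²¹⁰Pb inventory below z, is implemented as an independent cross-check.

**Kriging.** Ordinary (and universal, with polynomial drift) kriging from the
Matheron semivariogram γ̂(h) = Σ(zᵢ−zⱼ)²/2N(h), fitted by pair-count-weighted
least squares to spherical, circular, exponential, Gaussian or linear
families. Family selection predicts a seeded random 15% of points
leave-one-out and minimizes RMSE.

**Pettitt test.** U_t = Σ_{i≤t}Σ_{j>t} sign(x_j−x_i), K = max|U_t|,
p ≈ 2·exp(−6K²/(n³+n²)); the split regression evaluates both segment fits at
the change year, their gap being the step offset.

**Nitrogen loading.** Per decade: fertilizer = max(0, rate·area −
crop export)·leaching; wastewater = per-capita N·population partitioned by
septic/sewered transmission; atmospheric = Σ rate·area·(1−retention) over
land covers; livestock = Σ head·excretion·(1−loss). Totals are exact sums.

## Worked example

```bash
python examples/06_nitrogen_budget.py
```

```
decade   total kg N/yr   dominant source   fertilizer share
1930          67,940   livestock         0.00
1950         177,112   fertilizer        0.47
1970         579,199   fertilizer        0.79
1980         824,987   fertilizer        0.87
2010         535,392   fertilizer        0.88
```

Before synthetic fertilizer, harvest export exceeds application and livestock
dominates the budget; the fertilizer surplus then grows to ~87% of a total
that peaks around 1980 — the structural signature the isotope series record
as a post-1940 δ¹⁵N rise. The other examples (`examples/01…07`) run each
stage the same way; `07_full_pipeline.py` simulates a 12-site estuary and
prints six era-map means rising from 3.2‰ to 11.5‰ and a positive DIF at
every focal site.

The same pipeline is scriptable from the shell:

```bash
paleoscape simulate --seed 1 --input-dir fixture
paleoscape run-all  --seed 1 --input-dir fixture --outdir out
```

`out/report.json` is byte-identical across reruns with the same seed.

## Layout

```
src/paleoscape/   core types & I/O, synthetic generators, chronology,
                  isoscape, changepoint, nitrogen, pipeline, cli
examples/         one short narrative script per capability
tests/            unit, property and acceptance suites
docs/methods.md   models, assumptions, parameter choices, limitations
```
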