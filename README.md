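# azollatpc

Thermal performance curve fitting and climate suitability projection for
*Azolla*, the floating fern co-cultivated with rice as a nitrogen-fixing
biofertilizer.

Whether *Azolla*–rice farming is viable in a region depends first on
temperature: the fern grows fastest near a thermal optimum and dies off at
extremes.  This package implements the quantitative pipeline behind that
question, for researchers and agronomists assessing where (and under which
climate futures) *Azolla* cultivation is worthwhile:

1. **Harmonize** heterogeneous literature growth records — reported
   relative growth rates (RGR), biomass pairs, or doubling times — into a
   uniform table of per-day rates, via `RGR = ln(M₂/M₁)/Δt` and
   `RGR = ln 2 / DT`.
2. **Fit** an asymmetric piecewise-Gaussian thermal performance curve per
   species by maximum likelihood:

   ```
   P(T) = P_max exp(−a (T − T_opt)²),  T ≤ T_opt
   P(T) = P_max exp(−b (T − T_opt)²),  T > T_opt
   ```

   with Gaussian residual error and a study-level random effect on log peak
   height, `u_j ~ N(0, σ_study²)`, marginalized by adaptive Gauss–Hermite
   quadrature (an integrated-likelihood fit).
3. **Project** the fitted curve pixel-wise onto gridded annual-mean
   temperature (WorldClim bio1-style GeoTIFF) to map habitat suitability as
   predicted RGR, and summarize climate scenarios as regional means,
   difference maps and percent change.

A synthetic-data module generates multi-study datasets and temperature
rasters with known ground truth, so the whole pipeline is testable without
downloading anything.  See `docs/methods.md` for the statistical details.

## Worked example

Generate a synthetic literature-scale compendium (282 records across six
species, with known curve parameters), fit one species, and project the
fitted curve onto a temperature gradient and a +2.4 °C warmed version of
it:

```sh
azollatpc simulate --out records.csv --literature --seed 0
# wrote 282 records to records.csv

azollatpc fit --records records.csv --species A_filiculoides --out fit.json --seed 0
# A_filiculoides: p_max=0.1773 d^-1, t_opt=24.61 C, a=0.00528, b=0.00456
#   (loglik=294.172, n=149 records / 21 studies)

azollatpc simulate-raster --out current.tif --kind gradient --t-min 12 --t-max 38
azollatpc simulate-raster --out rcp85.tif --kind gradient --t-min 12 --t-max 38 --offset 2.4

azollatpc project --fit fit.json --current current.tif --future rcp85=rcp85.tif --out-dir proj
# A_filiculoides current: mean RGR 0.132 d^-1
# A_filiculoides rcp85: mean RGR 0.130 d^-1, change -0.00160 d^-1 (-1.22%)
```

Reading the numbers: the fitted optimum is 24.6 °C with a peak growth rate
of 0.177 d⁻¹ (the generating truth for this species was 24.5 °C and
0.18 d⁻¹ — the fit recovers it from 149 noisy records spread over 21
simulated studies).  The shallow rise coefficient `a` and steeper fall
coefficient `b` make the curve asymmetric: this species loses performance
faster above the optimum than below it, so a uniform +2.4 °C shift lowers
the regional mean RGR by 1.2% on this gradient — hot pixels lose more than
cool pixels gain.  `proj/` contains the suitability and difference GeoTIFFs
plus `summary.csv`/`summary.json` with the same numbers.

The same `fit`/`project` commands accept real data: a CSV/XLSX compendium
(with a YAML column map if the headers differ) and WorldClim-style current
and scenario rasters plus an optional 0/1 region mask (`--scale-factor 0.1`
if the layer stores tenths of a degree; `--weighted-mean` for cos-latitude
area weighting).

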