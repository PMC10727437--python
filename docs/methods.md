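# Methods

## The model

Growth of *Azolla* (a floating aquatic fern used as a rice biofertilizer)
responds unimodally to temperature.  We describe that response with a
four-parameter asymmetric piecewise-Gaussian thermal performance curve
(the Room model):

```
P(T) = P_max · exp(−a (T − T_opt)²)   for T ≤ T_opt
P(T) = P_max · exp(−b (T − T_opt)²)   for T >  T_opt
```

* `P_max` — peak relative growth rate (RGR), d⁻¹.  RGR is the per-day
  exponential rate `ln(M₂/M₁)/Δt`; doubling time converts as
  `RGR = ln 2 / DT`.
* `T_opt` — optimal temperature, °C.
* `a`, `b` — rise- and fall-side shape coefficients, °C⁻², both > 0.
  (Some summaries quote units of °C^−1/2 for these coefficients; that is
  dimensionally inconsistent with the exponent `a(T−T_opt)²` and we treat it
  as a typographical slip — the algebraic form above is what is
  implemented.)

The curve is continuous at the optimum, strictly positive, defined at all
temperatures, and asymmetric whenever `a ≠ b`.  It is descriptive, not
mechanistic: its job is to interpolate performance, not to explain enzyme
kinetics.

## Statistical model and fitting

One observation is a study-level mean RGR at one temperature treatment.
Literature compilations mix strains, culture conditions and experimenter
practice, so peak performance varies between studies.  We model this with a
multiplicative study-level random effect on peak height:

```
y_ij = P_max · exp(u_j) · s(T_ij) + ε_ij
u_j  ~ N(0, σ_study²)          (log peak-height deviation of study j)
ε_ij ~ N(0, σ_resid²)          (residual error)
```

where `s(T)` is the unit-peak curve shape.  The log-scale multiplier keeps
every study's peak positive; the placement on peak height (rather than on a
shape coefficient) matches the motivation — study-to-study variation in
maximum growth rate.

The study effects are nuisance parameters and are integrated out: the
marginal (integrated) likelihood of study *j* is

```
L_j = ∫ N(u; 0, σ_study²) · Π_i N(y_ij; P_max e^u s(T_ij), σ_resid²) du
```

evaluated by **adaptive Gauss–Hermite quadrature** (default 21 nodes).  The
adaptive rule recentres the nodes at the mode of each study's integrand
(found by a damped Newton iteration with analytic derivatives) and rescales
them by the curvature there.  This matters: with a typical residual SD of
0.03 d⁻¹ the conditional likelihood is much narrower than the prior on `u`,
and a prior-scaled rule at 21 nodes is accurate only to ~1e-3, while the
adaptive rule is accurate to better than 1e-9 (checked against both node
refinement and a 10⁶-draw Monte-Carlo marginalization in the test suite).
All accumulation is in log space, so the objective is finite for any valid
parameter vector.  At `σ_study = 0` the marginal collapses exactly to the
fixed-effects likelihood with all offsets at zero.

The integrated negative log likelihood is minimized over
`(log P_max, T_opt, log a, log b, log σ_resid, log σ_study)` with L-BFGS-B
under box bounds (`P_max ∈ [1e-4, 2]` d⁻¹, `T_opt ∈ [0, 50]` °C,
`a, b ∈ [1e-6, 1]` °C⁻², `σ ∈ [1e-5, 5]`), motivated by the 5–50 °C
experimental span and the magnitude of observed growth rates.  Log
transforms enforce positivity without constraints.  Optimization is
multi-start (default 8): the first start places `T_opt` and `P_max` at the
temperature and value of the maximum observed RGR; the rest jitter that
point with a seeded generator, so a fit is bit-for-bit reproducible given
the same configuration.  The best converged start wins; ties go to the
lower start index.  Species are fitted independently.

Reported SDs in source tables are carried through but not used as weights
by default; there is no heteroscedasticity structure in the model.  Profile
likelihood confidence intervals are not computed (the result JSON reserves
a field for them).

## Record harmonization

Raw records may carry a reported RGR, a biomass pair with times, or a
doubling time.  Precedence is reported > masses > doubling time; a reported
value is never altered, and the chosen path is recorded per record
(`rgr_source`).  Negative RGR (die-off at thermal extremes) is accepted —
the curve cannot predict it, but such records inform the fit through the
residual term.  Temperature cells holding day/night pairs or ranges
("30/20") are reduced to their arithmetic mean with the original preserved
in the conditions field.  Records with additional environmental
manipulations (CO₂, phosphorus, pH, light) are retained by default,
labelled, and can be excluded with a flag.  Column mapping from arbitrary
source headers is configuration-driven (YAML), since compilations differ in
layout.  Species labels come from a six-name controlled vocabulary; rows
that cannot be harmonized are logged, never silently dropped.

## Projection onto climate rasters

A fitted curve is applied pixel-wise to a single-band grid of annual mean
temperature (WorldClim bio1 style), giving predicted RGR per pixel — a
continuous productivity proxy for habitat suitability, not a binary range
map.  Scenario comparison is raster arithmetic:

* regional mean = unweighted arithmetic mean over valid pixels (a
  `weighted` flag enables cos-latitude area weighting);
* difference map = future − current, defined on the **intersection** of the
  two valid masks (a difference is undefined where either layer is
  missing);
* percent change = 100 × mean difference / current regional mean.

By construction `mean(difference map) = mean(future) − mean(current)` on
the shared mask, and the test suite checks this identity to 1e-12 together
with a brute-force per-pixel recomputation of every statistic.  Inputs must
share grid shape and CRS — resampling and reprojection are deliberately out
of scope so that no temperature is ever silently interpolated.  Grids
stored in scaled integer conventions (e.g. °C × 10) are handled by a
`scale_factor` applied to valid pixels on read.  Report-style rounding (3
decimals for rates, signed 2 decimals for percent) is applied only in
formatted output, never in computation.

GeoTIFF I/O is a deliberately small layer over `tifffile`: north-up affine
transform (pixel-scale + tiepoint tags), EPSG code (GeoKey directory) and a
declared nodata sentinel.  Rotated grids and exotic projections are not
supported.

## Synthetic data

The generator inverts the statistical model at known truth: per study a
lognormal peak multiplier, per observation Gaussian residual noise.
Defaults are `σ_study = 0.2` (log scale), `σ_resid = 0.03` d⁻¹, 20 studies
× 8 temperatures spanning 5–50 °C — roughly the scale and noise of the
literature compendium the pipeline targets.  A six-species synthetic
compendium mirrors that compendium's structure exactly in counts (40 +
149 = 189 records for *A. pinnata* and *A. filiculoides*, 282 across all
six species) with reference parameters `(P_max, T_opt, a, b)` =
(0.25, 24.5, 0.0155, 0.00344) for *A. pinnata* and
(0.18, 24.5, 0.005, 0.00495) for *A. filiculoides*; each simulated study
draws its own temperature scheme, as real studies do.  Synthetic rasters
are constant grids, linear gradients, or gradients with a nodata border,
with an optional uniform °C offset standing in for a future scenario
layer.

What the synthetic data do **not** emulate: digitization error from
plot-extracted values, publication bias across studies, within-study
replicate structure, non-Gaussian residuals, and any spatial pattern more
complex than a linear gradient.  Passing tests therefore demonstrate that
the machinery is correct under the model's own assumptions, not that the
model is adequate for any particular real compendium.

## Statistical power at compendium scale

A point worth stating plainly: with only 40 records under the default noise
conditions, the maximum-likelihood estimates of `T_opt` and `a` have median
absolute errors of roughly 0.6 °C and 30% across replicate datasets — the
data, not the optimizer, are the limit (at 10× the records the same
estimator's medians fall to ~0.34 °C and ~11%, and the 160-record recovery
check passes comfortably).  Single fits to small subsets should be read
with that sampling error in mind.

## Numerical choices and edge cases

* Quadrature node count must be odd (a node at the mode); default 21.
* The per-study Newton mode search is damped (step clipped to 1 on the log
  scale), clamped to |u| ≤ 30, and falls back to the prior SD for the
  rescaling when the curvature is non-negative.
* Convergence failure of every start raises an error carrying per-start
  diagnostics; the CLI maps it to exit code 3 (validation errors exit 2).
* Fits require ≥ 2 distinct temperatures (the compendium's inclusion
  criterion) and exactly one species per table.
* Duplicate (study, species, T, RGR) quadruples are kept and flagged as
  potential true replicates.

## Reproducing the published continental numbers

The continental summary statistics for Africa (current mean RGR 0.220 /
0.172 d⁻¹ for the two species, and the scenario differences) depend on the
actual WorldClim bio1 layers, the 2050 GISS-E2-R RCP 4.5/8.5 layers, and a
continent clip mask whose exact geometry (coastline source, island
inclusion) is not fully specified.  Reproducing them is an optional
external check: supply those rasters and a mask to `azollatpc project` and
compare regional means (expect agreement within ~0.01 d⁻¹ given mask
uncertainty).  At desk scale the pipeline's raster arithmetic is instead
verified exactly against independent per-pixel recomputation on synthetic
grids, and the percent-change arithmetic is verified against the published
summary-table values directly.
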