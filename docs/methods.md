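# Methods

## The allometric model

All interspecific analyses operate on species-level means: one row per
species with arithmetic means (raw mm scale) of intertegular distance (IT)
and of glossa, prementum and proboscis length, where proboscis = glossa +
prementum by definition on each specimen. The model is the power law

    ln(Y) = ln(a_f) + b · ln(IT),

natural logs throughout, with `a_f` a family intercept and `b` the scaling
exponent. Seven candidate mean structures are compared per response:
grouping by family, by tongue type (long = Apidae + Megachilidae, short =
the rest), or no grouping; with or without the ln(IT) slope; slope shared
or per-group (interaction). Designs use a cell-means parametrisation (one
intercept per group, no reference level), so exp(intercept) is directly
the group's `a`.

Fits are unweighted OLS across species: every species counts once
regardless of how many specimens produced its mean (a `weights` argument
exists for sensitivity analyses). Means are taken on the raw scale and
logged afterwards; geometric means are available as an option
(`log_scale=True`) but are not the default.

## AIC convention

Model ranking uses the Gaussian maximum-likelihood AIC *including* the
error variance as a parameter and keeping additive constants:

    AIC = n · ln(2π · RSS/n) + n + 2(k + 1),

k = number of mean-structure parameters. Conventions differ between
packages (some drop constants, some drop the variance parameter); only
differences within one convention are meaningful. Ties (ΔAIC < 1e-10,
e.g. two interpolating models on noise-free data) break toward fewer
parameters, on parsimony grounds. RSS = 0 has no finite ML AIC; `-inf`
is returned with a warning so a perfect fit still ranks first.

## SMA estimation and group tests

The standardized major axis summarises a bivariate scaling relationship
symmetrically in x and y: slope = sign(r) · s_y/s_x, intercept through the
centroid. Everything is built on one identity: the residual axis `y − bx`
and fitted axis `y + bx` are uncorrelated exactly when `b` is the SMA
slope. Hence:

* **One-sample slope test** (`test_slope_equals`): t test with n − 2 df on
  the residual/fitted correlation at the hypothesised slope. Slope CIs
  invert this test (exact pivot), not a normal approximation.
* **Common-slope LR test** (`test_common_slope`): the common slope
  minimises Σᵢ −(nᵢ − 2) · ln(1 − rᵢ(b)²) over b (Brent's method on a
  bracket spanning the group slopes, tolerance 1e-12); the minimised value
  is the statistic, compared to χ² with G − 1 df. The per-group
  multiplier nᵢ − 2 (rather than nᵢ) was chosen by calibration simulation
  — at 5 groups of 30 Gaussian observations it holds the empirical size at
  ≈0.055 versus ≈0.07 for nᵢ — and matches the convention of the standard
  SMA software in this field.
* **Elevation Wald test** (`test_common_elevation`): group intercepts
  âᵢ = ȳᵢ − b·x̄ᵢ at the common slope, compared through a Wald statistic
  whose covariance combines the per-group residual variance (estimated on
  nᵢ − 2 df; the small-sample correction again set by calibration
  simulation, empirical size ≈0.053–0.057 for n = 20–100) with the shared
  slope uncertainty Var(b̂) obtained from the numerical curvature of the
  profile deviance.

**Robust variant.** Outliers wreck variance-ratio slopes, so a robust mode
replaces the sample moments with a bivariate Huber/Maronna M-estimate of
location and scatter: points are weighted by Mahalanobis distance with a
Huber ψ, the distance cutoff mapped from the univariate k = 1.345 (95%
Gaussian efficiency) via the χ²₂ quantile transform, and the scatter
rescaled by the analytic Gaussian consistency factor. Test statistics are
plug-in versions of the classical ones with the same nominal reference
distributions. Published robust-SMA implementations differ in their
weighting scheme, so robust statistics computed here can differ in the
first decimal from other software on the same data.

## Intraspecific regressions

For each species with ≥ `min_n` (default 10) usable specimens, OLS of
ln(length) on ln(IT) across individuals, adding sex/caste as an additive
factor when at least two levels occur in that species. The reported
p-value is for the ln(IT) term specifically — the question is whether body
size predicts mouthpart length within a species — and the reported r² is
the model's coefficient of determination. No multiple-testing correction
is applied across species.

## Auxiliary estimators

* Body mass: Cane's IT = 0.77 · mass^0.405 (IT mm, dry mass mg), applied
  forward (`invert_body_mass`) and inverted (`estimate_body_mass`,
  mass = (IT/0.77)^(1/0.405)). The pair is exactly mutually inverse.
* Foraging distance: log₁₀(distance km) = intercept + slope · log₁₀(IT mm)
  per metric. The packaged constants file carries a provenance note per
  metric; the `typical_foraging` line is an explicitly labelled synthetic
  placeholder and the others should be verified against their source table
  before quantitative use. No headline result depends on these constants.

## The synthetic-data generator

The generator exists so the whole workbench is testable end to end without
any external download. Interspecific: per family, species ln(IT) is drawn
uniform over a configurable (min, max) IT range; each part's ln(length) is
the family line plus independent N(0, σ²) noise. Intraspecific:
individual ln(IT) is Normal around the species mean (SD `intra_sigma_it`,
default 0.08 ≈ 8% CV) and the response follows a within-species line of
slope `intra_slope` (default 1) with residual SD set by the closed form

    R² = b²σ_x² / (b²σ_x² + σ_e²)

inverted for σ_e at a configured target R².

`study_config()` packages the default study conditions: 5 families × 20
species (≈100 species), family IT ranges of roughly 0.8–6 mm chosen as
representative spans for North American members of each family, the
packaged coefficient table as truth, and per-part σ calibrated
*analytically* (`sigma_for_target_r2`, using the uniform-ln(IT) variance
decomposition) so the population model R² equals the reported
interspecific values 0.91/0.91/0.85. `study_intraspecific_config()` uses
24 species × 25 specimens with a within-species R² target of 0.36.

What the generator does **not** emulate: phylogenetic structure below the
family level, unequal species counts per family, measurement error in IT
itself, sexual dimorphism (unless configured), and taxa that genuinely
violate the family-level model (e.g. euglossines). Passing tests on
synthetic data therefore demonstrate that the statistical machinery
recovers the structure it assumes — rankings, coefficients, test sizes —
not that real bee data satisfy those assumptions, and the original
study's printed statistics are not reproduction targets for the synthetic
pipeline (its raw data are not redistributable).

## Numerical and design choices

* Degenerate inputs fail loudly: unknown families are rejected with the
  list of supported names (never coerced), non-positive lengths and
  zero-variance groups are errors naming the offending group/row, and a
  singular design (e.g. a one-species family under an interaction model)
  names the deficient group. Batch prediction never drops rows silently —
  unpredictable rows carry NaN plus a `reason`.
* The specimen-level invariant proboscis = glossa + prementum is enforced
  at 1% relative tolerance (measurement rounding), but the *predictor*
  never sums parts: each part has its own fitted coefficients.
* Extrapolation flags use packaged per-family IT ranges (synthetic
  defaults, documented in the constants file) and are configurable.
* Each generator call owns a single seeded `numpy` Generator; identical
  seeds give bit-identical tables.
* Simulation sizes in the test suite (100–1000 replicates, 20–30
  observations per group) are chosen to keep each check's Monte-Carlo
  error comfortably below its assertion tolerance.

## Known limitations

* Coefficients exist for five families only; Melittidae and Stenotritidae
  bees cannot be predicted and are rejected explicitly.
* Predictions are species-level; within-species individual prediction is
  explicitly out of scope (weak intraspecific signal, mean R² ≈ 0.14–0.4).
* Robust test statistics are plug-in approximations; their finite-sample
  size has been checked only for the classical variant.
* The foraging-distance constants require verification against their
  source before use in quantitative work (see above).
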