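# Methods

This note records the statistical model, the conventions and defaults behind
each stage, and the design choices made where the method description leaves
room — in enough detail that every number the package produces can be traced
to a formula and a parameter.

## Study layout and data model

The unit of analysis is a *site* (a survey transect) observed in two periods
(T0, default years 1995–1997; T1, default 2010–2012; both configurable).
Around each site, a categorical land-cover raster (ESRI ASCII grid, integer
codes, 0 = outside buffer) describes the landscape. Codes are partitioned
into a **natural** component (woodland, open woodland, shrubland, streams,
water bodies) and a **production** component (arable land with scattered
trees, annual dry crops, permanent pastures, annual irrigated crops,
permanent crops). Bird records (site, year, species) are pooled within each
period into distinct-species counts per habitat group: all species, woodland,
farmland, and steppe (open-grassland farmland specialists). Species tagged
`excluded` (aquatic birds, inadequately sampled by transects) are dropped
from every count. Steppe species count toward farmland when
`steppe_in_farmland=True` (default, since steppe birds are a farmland
subset); the flag exists because the species→group table is user input.

## Landscape metrics

All metrics are raster-native, computed on the buffer's cells.

* **Composition**: coverₖ = 100 · cellsₖ / buffer cells.
* **Compositional heterogeneity** per component: richness S (categories with
  ≥1 cell), Shannon diversity H = −Σ pᵢ ln pᵢ (nats), evenness H / ln S.
  Proportions pᵢ are relative to the *component's own* area, not the whole
  buffer, so the thin natural component is described on the same scale as the
  dominant production component. Evenness at S ≤ 1 is defined as 0 (the
  variable must attain 0, not be undefined, on single-category buffers);
  absent components score 0 on everything.
* **Configurational heterogeneity** per component: patches are maximal
  same-category connected components, 8-connectivity by default (the common
  default of raster landscape-metric software; 4-connectivity available).
  Largest patch index = 100 · max patch area / buffer area; mean patch size
  in ha; mean shape index = mean over patches of 0.25·P/√A with perimeter P
  in cell edges and area A in cells, so a square patch scores exactly 1.
  Patch perimeter counts edges against a different category, outside-buffer
  cells, or the grid border. **Edge density** counts each internal
  differing-category cell adjacency once (when at least one side belongs to
  the component), converted to metres per hectare of buffer; buffer and grid
  borders are excluded so buffer shape does not inflate edge estimates.

These conventions (Shannon rather than Simpson, unweighted shape index) are
the standard forms; each lives behind a single function so an alternative
definition is a one-function substitution.

## Transforms and matrices

Percent covers and the largest patch index are proportions: x/100 then
arcsin √x. Evenness is already in [0, 1] and gets the angular transform
directly. Diversity, cover richness, patch size, edge density and shape
index are continuous and get ln(x + 1); the +1 offset (configurable) is
needed because these metrics are legitimately 0 on sparse buffers. Spatial
analyses (Poisson, log link) use one period's transformed variables; temporal
analyses (Gaussian, identity link) use Δy = y(T1) − y(T0) against predictor
deltas. Deltas are taken on the *transformed* variables by default
(transform-then-difference keeps all deltas on comparable scales and avoids
re-transforming signed differences); raw-scale differencing is a switch,
since descriptive summaries of temporal change are conventionally reported on
the raw scale.

## Two-stage inference

Stage 1 forms all 2⁶ − 1 = 63 non-empty combinations of the six variable
sets; by symmetry each set occurs in exactly 2⁵ = 32 candidates and every
variable co-occurs with every other in at least one model. Each candidate is
fitted by maximum likelihood; AICc = −2LL + 2k + 2k(k+1)/(n−k−1) with k
counting intercept and slopes plus, for Gaussian models, the variance
parameter; the Gaussian LL is the exact profile-ML value
−n/2(ln 2π + ln(RSS/n) + 1), matching R's `logLik.glm`, so criteria are
comparable across software. A set is retained when its summed Akaike weight
exceeds 0.5. When no set passes, the pipeline reports that and skips stage 2.

Stage 2 enumerates every subset of the retained sets' variables (capped at
2²⁰ models; the cap must be raised explicitly). The null model is included:
it costs nothing and calibrates the weights when all effects are weak.
Within each model, VIFⱼ = 1/(1 − R²ⱼ) from regressing xⱼ on the model's other
predictors (VIF = 1 for a lone predictor), and the partial SD is
s*ⱼ = sⱼ √(1/VIFⱼ) √((n−1)/(n−p)) with p counting the mean-structure
coefficients *including the intercept* (the convention is exposed as the
`p` definition in `partial_sd`; counting the intercept makes p the column
dimension of the design matrix). Relative importance within a model is
|bⱼ s*ⱼ| / max|b s*|; ties for the maximum all score 1.0. Averaging is
**conditional**: coefficients and importances are averaged over the models
containing the variable with weights renormalised over those models, and the
variable's unconditional summed weight is reported alongside — conditional
averaging matches reporting importance "within the models where the variable
occurs", while zero-filled full averaging would shrink coefficients of rarely
selected variables toward 0 and conflate selection with effect size. For
Gaussian (temporal) models the standardized coefficient is additionally
divided by the response SD (toggleable), putting responses with different
variances on one scale; Poisson log-link coefficients are already on the log
scale. Standardized coefficients are invariant to affine rescaling of any
predictor, which the tests verify numerically.

Model dispersion (Pearson χ²/(n − p)) is attached to every fit; on data
simulated from the fitted family it averages ≈ 1, the usual adequacy check
for Poisson richness models.

## Spline correlogram

Values are centred and scaled; all pairwise products zᵢzⱼ at distances up to
`max_dist` (default half the maximum pairwise distance, avoiding the sparse
far tail) are regressed on distance with a clamped cubic B-spline basis whose
size is the equivalent degrees of freedom (default min(10, max(4, √n))),
knots at distance quantiles, estimates clamped to [−1, 1]. The 95% pointwise
envelope resamples *sites* with replacement B times (default 1,000),
dropping self-pairs, refitting on the fixed knot vector. Reported summaries:
e0 = ρ̂(0) and the x-intercept (first downward zero crossing, by linear
interpolation on the grid). Residual diagnostics use deviance residuals by
default (Pearson by flag); "no significant residual autocorrelation" is
operationalised as the residual envelope containing zero on ≥95% of the
distance grid, since the method itself prescribes no numeric rule.
Correlograms are invariant to rigid motions of the coordinates and affine
rescaling of the values, and seeded runs are bit-reproducible.

## Synthetic generator

The generator's defaults are the study conditions the analysis targets: 73
sites, two periods, 45×45-cell buffers of 50-m cells, ten categories with a
production-dominated Dirichlet composition (α = 0.25–0.35 for natural,
0.7–1.6 for production categories, giving natural covers of a few percent and
production covers dominated by annual crops and pastures, with realistic
between-site spread). Compositions are realised by seeded region growing:
each category receives ≈ target/aggregation seeds (default aggregation 60
cells ≈ 15 ha expected patches) and grows one 4-adjacent cell at a time,
deficit-weighted, until the largest-remainder targets are met exactly — so
realised covers match targets to within one cell, unlike threshold-on-noise
generators. Responses follow the same GLM structure the models fit:
η = β₀ + Σ βⱼxⱼ on transformed predictors, Poisson counts for spatial modes,
Gaussian deltas for temporal, plus an optional exponential-covariance
Gaussian field (Cholesky factorisation; adequate at these n) on the linear
predictor. The documented strong-effect sets (`STRONG_EFFECTS`) put
coefficients of magnitude 0.6–1.6 on one variable set per response group —
production composition for all/farmland/steppe, natural composition for
woodland — sized so a single 73-site realisation identifies the generating
set clearly without saturating every replicate. Survey records are emitted
so pooled distinct-species counts reproduce group targets exactly.

What the generator does *not* emulate: detection error and observer effects,
species' joint (community) structure, temporally autocorrelated land-cover
change, and non-raster cartography. Passing tests therefore demonstrate the
*statistical machinery* — metrics, screening, averaging, diagnostics — not
that real bird data meet the models' assumptions.

## Problem sizes and numerical choices

The test and acceptance runs use the generator at its default 73 sites with
50–100 replicates for recovery rates and B = 200–300 bootstrap resamples for
replicate-level correlogram checks (the default B = 1,000 is used for single
analyses); these sizes give Monte-Carlo error comfortably below the margins
being asserted. GLMs use IRLS (statsmodels) with tolerance 1e-10; rank
deficiency is detected via matrix rank and reported with the offending
columns from a pivoted QR; Gaussian fits use least squares directly. Known
limitations: the correlogram's e0 extrapolates the spline to distance zero
and can be unstable when short-distance pairs are scarce; conditional
averaging intentionally does not shrink rarely selected variables; and the
stage-1 screen inherits AICc's small-sample behaviour — with 24 variables
and n = 73 the global model burns a third of the degrees of freedom, which
is the regime the small-sample correction is for.
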