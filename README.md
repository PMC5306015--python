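# farmscape

Does farmland bird diversity respond to *what* a landscape is made of, or to
*how heterogeneous* it is? `farmscape` is a Python library for answering that
question the way landscape ecologists pose it: bird species richness around
survey transects is modelled against variables describing the **composition**
(percent cover of land-cover categories) and the **compositional** and
**configurational heterogeneity** of the *natural* (woodland, shrubland,
streams, water bodies) and *production* (crops, pastures, permanent crops)
components of the surrounding landscape, in two survey periods and as
temporal change between them.

It is aimed at ecologists and biostatisticians who want a tested, scriptable
version of this analysis — including a synthetic-data generator with known
ground truth, so every stage can be validated without field data.

## What it computes

**Landscape metrics** (per buffer, per component, on categorical rasters):
percent cover per category; cover richness, Shannon diversity
H = −Σ pᵢ ln pᵢ and Pielou evenness H/ln S; largest patch index, mean patch
size, edge density (m/ha) and mean shape index 0.25·P/√A, with patches as
8-connected components — 24 variables organised in six sets.

**Two-stage multimodel inference.** Spatial richness is modelled by Poisson
log-link GLMs, temporal change by Gaussian GLMs. Stage 1 fits all 2⁶−1 = 63
combinations of the six variable sets and scores each set by its summed
Akaike weight w⁺ᵢ = Σ wᵢ over the candidates containing it, with
wᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2) from AICc = −2LL + 2k + 2k(k+1)/(n−k−1). Sets
with w⁺ᵢ > 0.5 are carried into stage 2, which enumerates all subsets of their
variables and model-averages each variable's **partial standardized
coefficient** bⱼ·s*ⱼ, where

&nbsp;&nbsp;&nbsp;&nbsp;s*ⱼ = sⱼ · √(1/VIFⱼ) · √((n−1)/(n−p)),

together with its within-model **relative importance**
|bⱼ s*ⱼ| / max<sub>m</sub> |b<sub>m</sub> s*<sub>m</sub>| — a standardization
that stays meaningful under multicollinearity.

**Spatial diagnostics.** Spline correlograms (pairwise products of
centred-scaled values regressed on distance with a cubic B-spline smoother)
with 95% pointwise envelopes from 1,000 site-bootstrap resamples, applied to
raw responses and model residuals to verify the covariates absorbed the
spatial structure.

**Synthetic data.** Dirichlet compositions realised by seeded region growing
(aggregation parameter = expected patch size), GLM responses with known
coefficients, optional exponential-covariance spatial noise, and survey
records whose pooled richness reproduces group targets exactly.

## Worked example

`examples/04_model_selection.py` simulates a 73-site study whose richness is
generated from the production-composition variables only, then runs both
stages:

```
stage 1 - summed Akaike weights over 63 candidate models:
            set  w_plus  retained
       nat_comp   0.009     False
      prod_comp   1.000      True
 nat_compos_het   0.058     False
prod_compos_het   0.054     False
 nat_config_het   0.020     False
prod_config_het   0.021     False

stage 2 - averaged over 32 models (global pseudo-R2 0.72):
              variable  coefficient  importance  sum_weight
annual_irrigated_crops       -0.299       1.000       1.000
arable_scattered_trees       -0.232       0.776       1.000
    permanent_pastures       -0.186       0.622       1.000
      annual_dry_crops        0.161       0.539       1.000
       permanent_crops        0.096       0.324       0.923
```

The screen gives the generating set (production composition) w⁺ᵢ = 1.00 and
retains nothing else; the averaged partial standardized coefficients rank the
individual crops by effect size, with the strongest variable at importance
1.0 by definition. The other examples cover landscape simulation and metrics
(`01`, `02`), survey pooling (`03`), correlograms (`05`) and the full
pipeline (`06`); each prints what its numbers mean.

A thin CLI mirrors the library for shell use:

```bash
farmscape run --config configs/demo.yaml --out out/
farmscape simulate --seed 1 --n-sites 10 --out sim/
farmscape metrics --raster-dir sim/rasters --out metrics.csv
```

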