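# Methods

This note documents the models implemented in `breedsync`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## NDVI cleaning

Satellite NDVI composites carry weather/snow/water artifacts, so location
series are cleaned before any predictability statistic is computed. The
fixed order of operations is: winter zeroing (northern locations only) →
negative-run removal → spike correction → pixel aggregation. Zeroing comes
first because winter negatives at snow-covered sites are expected values,
not anomalies; removing negative runs first would discard those pixels for
the wrong reason.

* **Winter zeroing.** Negative values at periods inside a configurable
  winter window are replaced with exactly 0. The window may span at most
  half the annual cycle; the default for bi-monthly data is November–April
  (periods 20–23 and 0–7), the maximal fixed six-month window inside the
  permitted November–May span. Real winters vary by pixel and year; a fixed
  window is a deliberate simplification, exposed in config.
* **Negative runs.** A pixel with ≥ 3 consecutive strictly negative values
  (in time order, across year boundaries) is removed as unusable. Zero is
  not negative.
* **Despiking.** A jump of > 0.25 NDVI units relative to the previous value
  counts as an anomaly only if the series returns rapidly: within one step
  to within 0.25 of the pre-jump level (single spike, replaced by the flank
  mean), or within two steps (double spike, the two values replaced by
  linear interpolation between the flanks, weights 2/3–1/3 and 1/3–2/3).
  "Rapid return" within one time step is our operationalization for the
  bi-monthly cadence; persistent level shifts are deliberately left alone.
  The pass runs once, left to right, using already-corrected values as left
  flanks.
* **Aggregation.** Retained pixels are averaged per (year, period). A
  location keeping fewer than 50% of its pixels is excluded; exactly 50% is
  kept (strict "< 50%" reading of the exclusion rule). The across-years mean
  annual profile is available as a separate descriptive output
  (`LocationSeries.across_years_mean`), but the predictability statistics
  are computed on the full year-resolved series — collapsing across years
  would destroy the inter-annual signal that constancy measures.

## Colwell's predictability statistics

Observations are discretized into `s` ordinal states and tabulated against
`t` time-of-year categories, pooled across years. With the usual `0·log 0 = 0`
convention, constancy `C = 1 − H(Y)/log s`, contingency
`M = (H(X) + H(Y) − H(XY))/log s`, predictability `P = C + M`. Natural logs
are used internally; the normalization by `log s` makes the results
base-free, which the tests verify against a log₂ recomputation.

The state count and binning scheme are free parameters (defaults: `s = 8`,
equal-width bins over the observed local range; equal-width bins over
[−1, 1] and quantile bins are alternatives). Discretization loses
information, and different choices shift the absolute C/M values; comparing
locations under a common scheme is the intended use. Bins are lower-closed:
a value on an interior edge joins the lower bin, and the series maximum
joins the top bin.

## Phylogeny handling and trait-evolution models

Population tips are grafted onto species tips as polytomies with branch
length `ε = 1e-6 × tree height` (a zero request is replaced by the default
with a warning): conspecific populations then share essentially the whole
species history while V stays positive definite. The Brownian covariance is
`V_ab = depth of MRCA(a, b)`; Pagel's λ multiplies the off-diagonal entries
only.

Trait-evolution models (BM, λ, white noise) are fitted by maximizing the
MVN likelihood with mean `z0·1` and covariance `σ²·V(model)`. `z0` and `σ²`
have closed-form profile estimates; λ is optimized on [0, 1] by bounded
scalar search (tolerance 1e-8, with explicit boundary checks because the
bounded optimizer can stop short of an edge). All likelihoods go through
Cholesky factorization — no explicit inverses — and the tests pin them to
explicit-inverse MVN density oracles on small trees to 1e-8, and the λ ML
to an independent implementation. AIC parameter counts: BM and white k = 2
(σ², z0), λ k = 3; counting is stated explicitly because conventions vary.
λ = 1 reproduces BM exactly; λ = 0 is likelihood-equivalent to white noise
on ultrametric trees (V = h·I absorbs into σ²). Estimates above 1 are not
searched: they can break positive-definiteness. Non-ultrametric input trees
are accepted; the λ ≡ white equivalence then holds only approximately. The
compared model set {BM, λ, white} is configurable; an OU model is out of
scope.

## PGLS regression and model comparison

For fixed λ the GLS solution is computed by whitening with the Cholesky
factor of V(λ) and solving the least-squares problem; λ is then profiled by
ML per candidate model (re-estimated for each model, with a fixed-λ
option). Conventions, each chosen where the field has no single standard:

* σ² reported is the ML estimate (RSS/n); standard errors for inference use
  the n − p denominator, and P values are two-sided Student-t with n − p
  degrees of freedom (REML-style SEs, ML point estimates — `reml_se=False`
  switches to pure ML).
* `k` counts β, σ² and λ (when estimated); `AICc = AIC + 2k(k+1)/(n−k−1)`.
* Treatment coding with fixed reference levels: diet reference = browser,
  calf behaviour reference = follower; gregariousness enters as a numeric
  1–5 score; latitude enters as absolute latitude (the hypothesis concerns
  distance from the equator). `a * b` expands to `a + b + a:b` and
  interactions always carry their main effects (hierarchy rule).
* Adjusted R² is computed on the λ-whitened scale as the squared
  correlation between whitened fitted and observed values, adjusted for
  model size — there is no canonical PGLS R².
* The response is the natural log of birth-season length in days.

The default candidate set is the 23 formulas combining contingency,
constancy, latitude, diet, calf behaviour and gregariousness (with the
contingency×constancy and diet interactions). Formulas whose columns are
missing from a given trait table are skipped with a logged reason and the
comparison proceeds over the estimable set.

## Moran's I diagnostics

Spatial weights default to k-nearest-neighbour (k = 4) adjacency on
great-circle distances, symmetrized by the max rule and row-standardized;
inverse-distance weights are the alternative (coincident points receive an
epsilon offset). Moran's I is tested with the standard deviate
`z = (I − E[I])/√Var(I)` under the normality assumption,
`E[I] = −1/(n−1)`, two-sided; a 999-permutation null is available as a
cross-check and agrees with the z test on Gaussian data in the tests. The
neighbourhood definition is a reported configuration choice, not an
estimate.

## Synthetic data: what it emulates, and what it does not

The generator exists so every stage has inputs with known ground truth.

* **NDVI.** A raised cosine over the year (controllable peak period) sets
  seasonality; a per-year random amplitude multiplier (CV 0.15) plus white
  observation noise (SD 0.02) set inter-annual variability. The two noise
  sources let contingency and constancy be tuned semi-independently,
  matching their observed negative correlation. Defaults — 27 years ×
  24 bi-monthly periods, baseline 0.45, amplitude 0.30 — emulate a
  multi-decade record over a vegetated site with the trough safely positive.
  Injected anomalies (isolated downward spikes of 0.35–0.6, negative runs
  of length 3–5, winter negative dips) are recorded in a ground-truth
  ledger; the base signal and the anomalies use separate seeded RNG
  streams, so the ledger indexes exactly the values that differ from the
  anomaly-free series. Not emulated: spatial pixel correlation, phenology
  trends and double growing seasons, cloud/QA structure, or real geography.
  Passing tests show the cleaning rules recover known injected artifacts;
  they do not certify performance on real GIMMS data.
* **Trees and traits.** Species trees are pure-birth (Yule) trees with tip
  branches extended by one extra exponential waiting time so all branch
  lengths are strictly positive. Responses follow
  `log(birth-season length) = 9.33 − 11.53·M − 6.18·C + 7.67·M·C + ε`,
  `ε ~ MVN(0, 0.8²·V(λ=0.3))`, with contingency ~ U(0, 0.5) and constancy
  ~ U(0, 1) — the published best-model coefficients as generating truth on
  a realistic signal scale. The linear model is unbounded, so simulated
  responses can exceed the 1–365-day range observed in real data at the
  low-predictability corner of covariate space; recovery analyses work on
  the log scale throughout. Life-history covariates (diet, calf behaviour,
  gregariousness, latitude, coordinates) are optional additions drawn
  independently of the response — pure-noise competitors for model
  selection, without the phylogenetic conservatism real life-history traits
  show.

## Validation results the package computes

`breedsync.diagnostics` re-derives these; the test suite asserts them.

* Coefficient recovery (200 datasets, 70 populations on grafted 35-species
  Yule trees, λ = 0.3, σ = 0.8): mean estimates within 3 Monte-Carlo SEs of
  each generating coefficient; 95% CI coverage ~0.92–0.96.
* Model selection: the generating interaction model attains the lowest
  AICc in ~72% of those replicates when compared over the estimable
  candidate set (interaction, additive, and the two single-covariate
  models). When i.i.d. life-history noise covariates are added and the full
  23-formula set is compared, the strict first-place rate drops to ~40%:
  the true model then loses about a quarter of replicates to its own
  supersets (truth + one noise covariate), the familiar overfitting
  tail of information-criterion selection. The additive-family loss rate is
  unchanged; this is a property of AICc among nested supersets, not of the
  implementation.
* λ recovery (Yule trees, 128 tips, 200 replicates): mean |λ̂ − λ| ≈ 0.02
  at λ = 0 and ≈ 0.001 at λ = 1 (boundary piling), but ≈ 0.12 at λ = 0.5,
  whether trees are redrawn per replicate or fixed. The ML λ point
  estimator simply has that much sampling spread at this design — the
  implementation agrees with an independent reference to 1e-5 — so a
  sub-0.1 mean absolute error at λ = 0.5 is not attainable at n = 128, and
  the corresponding check is expected to fail by that margin.
* Moran's I on i.i.d. values matches `E[I] = −1/(n−1)` within Monte-Carlo
  error, and the normality z test agrees with the permutation null.

## Degenerate inputs and tie-breaks

Constant series: equal-width discretization puts everything in state 1
(C = 1); the quantile scheme refuses with an error. Frequency matrices need
`Z > 0` and `s ≥ 2` (C is undefined at s = 1). Zero-variance values are
errors for Moran's I and for OLS slopes. A noiseless PGLS fit returns
σ̂² = 0 with infinite t statistics rather than failing. `n ≤ p + 2` is
rejected up front (the AICc denominator must stay positive). Collinear
designs raise rather than silently pseudo-inverting.

## Problem sizes

The built-in simulations use 200 replicates for coefficient recovery and
model selection (n = 70 populations), 200 replicates per λ value at 128
tips for λ recovery, and 1000 simulations for the Moran null — sizes at
which the Monte-Carlo error bands quoted above are meaningful while the
whole suite stays interactive.

## Known limitations

* No GIS: polygons, water masks and pixel extraction are upstream concerns;
  pixels arrive pre-flagged (`removal_reason="water"`) if masked.
* The winter window is fixed per run, not per pixel-year.
* No OU or measurement-error models; no spatial regression (the Moran
  diagnostic is a check, not a correction).
* λ is searched on [0, 1] only; estimates that would exceed 1 are reported
  as 1.
* The synthetic trait generator draws covariates i.i.d. across tips;
  real environmental covariates are themselves phylogenetically and
  spatially structured.
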