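# breedsync

Tools for asking why some ungulate populations give birth within a few
weeks while others spread births over most of the year. The working
hypothesis is that breeding synchrony tracks the *predictability* of
resource availability: populations in strongly seasonal habitats should
compress their birth season into the short window of peak resources, while
populations in habitats with large year-to-year variation should spread
their bets. `breedsync` implements the full analysis chain needed to test
this comparatively, from satellite vegetation time series to
phylogenetically corrected regression, and ships a synthetic-data module so
every stage can be exercised and validated without external data.

## What it computes

**Environmental predictability (Colwell's statistics).** NDVI time series
(bi-monthly composites over many years) are cleaned — winter-snow negatives
zeroed for designated northern sites, pixels with three or more consecutive
negative values removed, spikes larger than 0.25 NDVI units with a rapid
return interpolated away, pixel series averaged per location (locations
keeping < 50% of pixels are excluded) — then discretized into *s* states
tabulated against time-of-year category. With column totals `X_j`, row
totals `Y_i` and grand total `Z`:

    H(X)  = -Σ_j (X_j/Z) log(X_j/Z)          (time entropy)
    H(Y)  = -Σ_i (Y_i/Z) log(Y_i/Z)          (state entropy)
    H(XY) = -Σ_ij (N_ij/Z) log(N_ij/Z)       (joint entropy)

    constancy      C = 1 - H(Y)/log s        (inter-annual stability)
    contingency    M = (H(X)+H(Y)-H(XY))/log s   (strength of seasonality)
    predictability P = C + M

All three lie in [0, 1]; `P = C + M` holds algebraically.

**Phylogenetic regression.** Populations are grafted onto a species-level
phylogeny as shallow polytomies (branch length ~0), giving a population
covariance matrix V of shared root-to-MRCA path lengths. The log of birth
season length (days) is regressed on contingency, constancy, their
interaction and life-history covariates by PGLS with residuals
`MVN(0, σ²V(λ))`, where Pagel's λ scales the off-diagonal of V and is
estimated by maximum likelihood on [0, 1] for each candidate model.
Candidate formulas are ranked by `AICc = AIC + 2k(k+1)/(n-k-1)`.
Trait-evolution models (Brownian motion, λ, white noise) are compared the
same way, and Moran's I with the normality-assumption standard deviate
checks the data and the best-model residuals for residual spatial
structure.

## Worked example

Clean one synthetic location (six pixels, 27 years, with injected spikes),
compute its predictability, and check that PGLS recovers known generating
coefficients:

```python
import numpy as np
from breedsync import (NdviGenConfig, generate_pixel_series,
                       smooth_location, location_predictability)
from breedsync.diagnostics import coefficient_recovery, recovery_summary

cfg = NdviGenConfig(n_years=27, spike_rate=0.01, seed=11)
pixels, ledger = generate_pixel_series(cfg, 6, location_id="serengeti_like")
loc, qc = smooth_location(pixels)
res = location_predictability(loc.flat(), np.tile(np.arange(24), 27), n_states=8)
print(f"spikes corrected: {qc.n_spikes_corrected} (injected: {len(ledger)})")
print(f"C = {res.constancy:.3f}  M = {res.contingency:.3f}  P = {res.predictability:.3f}")

summary = recovery_summary(coefficient_recovery(n_reps=50, seed=5))
print(summary.round(3).to_string(index=False))
```

Output:

```
spikes corrected: 39 (injected: 41)
C = 0.018  M = 0.778  P = 0.797
                 term   true  mean_estimate  mc_se   bias  coverage
            Intercept   9.33          9.393  0.123  0.063      0.92
          Contingency -11.53        -11.272  0.357  0.258      0.92
            Constancy  -6.18         -6.183  0.181 -0.003      0.90
Contingency:Constancy   7.67          7.166  0.584 -0.504      0.94
```

The despiker found 39 of the 41 injected anomalies. The strongly seasonal
synthetic habitat scores high contingency (M = 0.78) and low constancy
(C = 0.02): its state is almost fully determined by time of year but
varies between years. The recovery table shows the PGLS estimator is
approximately unbiased for the generating coefficients (bias within
Monte-Carlo error; ~95% CI coverage near nominal at 50 replicates).

A command-line interface mirrors the stages
(`breedsync simulate | ndvi-smooth | colwell | fit-evo | pgls | moran |
run-all`); `run-all` executes the whole pipeline from a YAML config and
writes the QC report, per-location C/M/P table, evolutionary-model and
AICc model-comparison tables, best-model coefficients, Moran diagnostics
and the contingency-constancy prediction surface, each stamped with the
config hash.

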