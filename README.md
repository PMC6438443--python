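# moranwave

Timescale-specific analysis of spatial synchrony in ecological (and
other) spatiotemporal data: which drivers synchronize spatially
separated populations, at which timescales, and how do multiple drivers
interact?

Spatially separated populations often fluctuate in step. When the cause
is spatially correlated environmental forcing rather than dispersal,
this is the *Moran effect*. Real systems typically have several
candidate drivers — climatic forcing, predation, resource dynamics —
whose effects can be timescale-specific and phase-lagged, and whose
mutual alignment can reinforce or cancel. Correlation-based tools miss
all three features. `moranwave` provides a wavelet toolkit for analysts
of annual spatiotemporal panels (N locations × T years) that handles
them directly.

## What it computes

Given cleaned panels `x_n(t)` and their complex Morlet transforms
`W_{n,σ}(t)` on a geometric timescale grid:

- **Wavelet mean field (WMF)** `r_σ(t) = (1/N) Σ_n w_{n,σ}(t)` of
  power-normalized transforms, whose magnitude surface displays
  synchrony by time and timescale, and the **mean squared synchrony**
  `{|r_σ(t)|²}_t`. The **phasor mean field (WPMF)** does the same with
  unit-magnitude transforms, is bounded by 1, and is significance-tested
  against a Monte-Carlo uniform-phase null.
- **Spatial coherence** `Π_σ = |⟨w⁽⁰⁾ w̄⁽¹⁾⟩| / √(⟨|w⁽⁰⁾|²⟩⟨|w⁽¹⁾|²⟩)`
  between two variables — a timescale-specific association measure that
  detects phase-lagged relationships, with Fourier-surrogate band tests.
- **Wavelet linear models**
  `w⁽⁰⁾_{n,σ}(t) ≈ β₁(σ) w⁽¹⁾_{n,σ}(t) + … + β_K(σ) w⁽ᴷ⁾_{n,σ}(t)`
  with complex timescale-dependent coefficients (magnitude = strength,
  argument = phase lag), fitted by least squares (equivalently,
  coherence-maximizing), plus surrogate drop tests,
  leave-one-location-out cross validation, exhaustive subset selection,
  phase diagnostics, and a spatial permutation test of local
  association.
- **Wavelet Moran theorem**: `{|r⁽⁰⁾_σ(t)|}_t ≈ {|r⁽ʰ⁾_σ(t)|}_t |Π⁽⁰ʰ⁾_σ|²`
  — observed synchrony ≈ model synchrony × squared model–response
  coherence — giving predicted-synchrony surfaces and the fraction of
  band synchrony a model explains.
- **Synchrony attribution theorem**: exact decomposition of
  model-explained synchrony into per-driver terms `|β_k|²{|r⁽ᵏ⁾|²}` and
  pairwise interaction terms `2 Re[β_j β̄_k ⟨r⁽ʲ⁾ r̄⁽ᵏ⁾⟩]` (which can be
  negative), plus surrogate randomizations that empirically isolate the
  contribution of between-driver alignment.
- A **synthetic-data module** generating fully specified test scenarios:
  a two-driver construction with tunable driver phase offset, an AR(1)
  Moran-theorem test bed, and generic sinusoid-plus-noise panels.

## Worked example

`examples/04_moran_attribution.py` builds the two-driver construction
(26 locations, 60 years; two drivers sharing a 20-year periodicity, one
acting inverted, the other inverted with a 5-year lag), fits the
two-predictor wavelet model of the jointly driven population, and
partitions its band (4–30 y) synchrony:

```
phi = 0.0: fraction of band synchrony explained = 0.664
  alpha: +0.269
  beta_lagged: +0.112
  interactions: +0.283 (reinforcing)
phi = 1.0: fraction of band synchrony explained = 0.083
  alpha: +1.052
  beta_lagged: +1.104
  interactions: -2.073 (counteracting)

randomizing away driver alignment: surrogate model synchrony is 60% of
observed (one-sided p = 0.0459)
```

At `phi = 0` the drivers' effects are in phase: the model explains two
thirds of the population's band synchrony, and nearly half of that
comes from the interaction term — the drivers reinforce. At `phi = 1`
their effects oppose: individual terms are large but the interaction
term cancels them, and almost no synchrony survives to be explained.
The randomization confirms the interaction empirically: replacing one
driver with surrogates that keep its own synchrony but scramble its
alignment with the other drops model synchrony to 60% of observed.

The other examples show mean fields with significance contours (01),
lag recovery from cross-wavelet phase (02), model selection discarding
a pure-noise decoy (03), and the classical AR(1) Moran theorem (05).

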