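# Methods

This note documents the models and procedures implemented in
`moranwave`, the numerical choices behind them, and what the synthetic
test bed does and does not establish about real data.

## Data model and cleaning

The basic object is an `N × T` panel: one variable measured at `N ≥ 2`
locations over `T ≥ 4` consecutive years. Missing values are rejected
at construction; the package does no imputation or temporal
aggregation (monthly-to-annual compilation of survey data is upstream
of this toolkit).

`boxcox_clean` processes each location independently: an additive
shift to positive support (zero if the series is already positive,
otherwise `-min + 1e-3·range`, placing the minimum just above zero — a
minimal shift keeps the Box-Cox exponent identifiable), a Box-Cox
transform with exponent chosen by profile log-likelihood on a grid
(default `[-5, 5]` step `0.01`; grid search over a wide range is robust
where a numeric optimizer can stall on flat likelihoods), a linear
detrend against the year axis, and standardisation to mean 0, variance
1 (population variance). Order of operations is shift → transform →
detrend → standardize: detrending the *transformed* series is the
standard practice for spectral preprocessing, since trends in skewed
raw data are distorted by the power transform. Likelihood (rather than
a normality statistic) selects the exponent; on simulated log-normal
data the grid estimate agrees with the continuous MLE to the grid
step. Constant series are a hard error naming the location.

## Wavelet transform

The continuous wavelet transform uses a complex Morlet kernel

    ψ_{σ,t}(u) = σ^{-1/2} π^{-1/4} · exp(i 2π f0 (u-t)/σ) · exp(-(u-t)²/(2σ²)),

applied as a direct truncated convolution `W_σ(t) = Σ_u x(u) ψ̄_{σ,t}(u)`
with support cut at `|u − t| > 4σ`. Direct convolution (rather than an
FFT product) keeps edge behaviour explicit and exact at the series
lengths the package targets (tens of years); cost is negligible there.
Kernel matrices are cached per `(T, grid, f0)`.

Parameters:

- `f0 = 1` (default): the magnitude response to a pure sinusoid of
  period `P` then peaks within one grid step of `σ = P`, so the
  timescale axis reads directly as oscillation period in years.
- Timescale grid: geometric, default ratio 1.05, from `σ_min = 2`
  years (the annual Nyquist limit) to the largest grid point `≤ T/2`.
- Transforms require per-location zero mean (enforced), since the mean
  otherwise leaks into long timescales.

Edge handling: a cell `(t, σ)` is flagged in the cone-of-influence
(COI) mask when the kernel, clipped by the series boundary, retains
less than 99% of its untruncated L2 norm. Two consequences of this
strict rule at short records deserve note. First, for `T = 60` no cell
passes the 1% criterion at timescales above ≈ 18 years, so statistics
that stack cells per timescale (regression fits, coherence means)
fall back to the full time axis at timescales whose non-COI set is
empty; at such timescales all locations share the same attenuation, so
ratio statistics are essentially unaffected. Second, mean-field
summaries (`msq`, and every Moran/attribution band aggregate built on
them) average over the *full* time axis at every timescale: a uniform
cell set keeps per-timescale values comparable across the grid,
whereas a per-timescale exclusion rule makes neighbouring timescales
average over radically different cell sets (four mid-series cells at
σ ≈ 18, the whole axis at σ ≈ 20) and displaces peak estimates. Under
the truncated-convolution transform, edge cells are amplitude-
*attenuated* — a truncated kernel loses mass and can only shrink
`|W|` — so including them is conservative: they cannot manufacture
synchrony.

Normalizations: `phasor` divides each cell by its magnitude (pure
phase information; zero cells stay zero); `power` divides each
location by the square root of its mean squared magnitude over all
cells, so per-location mean power is 1 while the distribution of power
across time and timescale is preserved.

## Mean fields and significance

The wavelet mean field (WMF) averages power-normalized transforms over
locations; the phasor mean field (WPMF) averages phasors and is
bounded by 1, reaching 1 exactly where all locations share a phase.
The WMF magnitude is *not* bounded by 1. The per-timescale time
average of squared magnitude is the mean squared synchrony; band
aggregation weights grid timescales equally (uniform in log timescale
on the geometric grid).

WPMF significance uses a Monte-Carlo null of `N` independent uniform
phasors (default 10,000 draws, seeded); for `N = 26` the 5% threshold
is ≈ `√(ln 20 / 26)` ≈ 0.34, matching the Rayleigh limit. Thresholds
are pointwise per cell with no multiple-testing correction — contour
displays are exploratory, not family-wise tests.

## Spatial coherence and surrogates

Coherence normalizes the mean cross-product of two power-normalized
transform sets per timescale, over the same cells in numerator and
denominator, so `Π_σ ∈ [0, 1]` holds exactly (a global normalization
could exceed 1 and is not used). The argument of the mean
cross-product is the typical phase difference at that timescale; a
consistent lag `τ` of a `σ`-periodic influence appears as phase
`2πτ/σ`.

Significance testing uses Fourier surrogates built in the time domain
(then re-transformed, preserving exact spectral structure):
independent phase draws per location destroy spatial synchrony;
a single shared draw per variable preserves all within-variable
cross-spectra — the variable's entire synchrony structure — while
destroying its relationships with other variables
("spatially synchronous surrogates"). Zero and Nyquist coefficients
are left untouched, so each location's sample mean and variance are
preserved exactly. Band p-values aggregate the statistic by an
unweighted band mean, then rank the observation among surrogates with
the `+1` correction, `p = (1 + #{surrogate ≥ observed})/(1 + count)`,
guaranteeing `p > 0`. Under the null the test is calibrated: the
acceptance suite measures type-I error at nominal 5% within
[0.02, 0.09] across 200 replicates. Amplitude-adjusted (AAFT-type)
surrogates are not provided; Box-Cox cleaning is assumed to
normalize marginals first.

## Wavelet linear models

At each timescale, coefficients solve the complex least-squares
problem over all stacked included (location, time) cells via normal
equations, with ridge jitter `1e-10` (scaled by the mean Gram
diagonal) for numerical rank safety; condition numbers above `1e10`
after jitter raise an error naming the predictor set — silent
collinearity would corrupt downstream attribution. Least squares
projects the response onto the predictor span, which simultaneously
maximizes the spatial coherence between response and fitted
combination at every timescale; fitted-model coherence therefore
dominates every single predictor's coherence (asserted in tests).

Model assessment:

- **Drop tests.** The statistic is the band-mean model–response
  coherence of the full model. The null replaces the *dropped*
  predictor's time-domain panel by synchrony-preserving surrogates,
  re-transforms, and refits the full model — surrogating the tested
  predictor eliminates exactly its relationships with the response and
  the other predictors while retaining its own spectra and synchrony.
- **Cross validation.** The exchangeable replicate is the location:
  leave-one-location-out, scoring the held-out cells as
  `1 − Σ|w⁽⁰⁾ − fit|²/Σ|w⁽⁰⁾|²` over included (t, σ ∈ band) cells,
  averaged over locations. Irrelevant predictors cannot materially
  inflate this out-of-sample score.
- **Selection.** Exhaustive enumeration of predictor subsets up to
  `max_k = 5`; a subset is retained only if every predictor's drop
  test has `p ≤ α` (default 0.05); retained subsets are ranked by
  cross-validation score, with subsets within 90% of the top score
  flagged as near-top.
- **Phase diagnostics.** The fitted coefficient phase is compared with
  the circular mean phase of the response–predictor cross-product; for
  genuine, consistent associations the two estimators agree.
- **Locality.** A spatial permutation test re-pairs predictor and
  response locations at random (uniform permutations); small p-values
  indicate the association is location-matched rather than purely
  regional.

## Moran theorem and synchrony attribution

The model mean field `r⁽ʰ⁾ = Σ_k β_k r⁽ᵏ⁾` (equal, by linearity, to
the location average of the fitted transforms; both routes are
computed and checked to `1e-10`). The Moran relation

    {|r⁽⁰⁾_σ(t)|²}_t ≈ {|r⁽ʰ⁾_σ(t)|²}_t · |Π⁽⁰ʰ⁾_σ|²

is exact when the response equals the model fit and becomes an
inequality (observed > predicted) when unmodeled synchronizers act.
Its band-aggregated ratio is the fraction of synchrony explained;
`|Π_σ| · |r⁽ʰ⁾_σ(t)|` is the predicted-synchrony surface comparable
cell-by-cell with the observed mean-field magnitude.

Attribution expands `|r⁽ʰ⁾|²` exactly into per-driver terms
`|β_k|² {|r⁽ᵏ⁾|²}` and pairwise cross terms
`2 Re[β_j β̄_k ⟨r⁽ʲ⁾ r̄⁽ᵏ⁾⟩_t]`, each scaled by `|Π|²` and the observed
band denominator, so components sum to the total by construction
(conservation is asserted to `1e-8`). Cross terms are signed:
favourably phased drivers reinforce (positive), opposed drivers cancel
(negative), and with strongly opposed drivers the individual terms and
the (negative) interaction term can each exceed the small total in
magnitude.

Interaction randomization rebuilds the model mean field with the
*original* coefficients while replacing one driver's panel by
surrogates — keeping β isolates the effect of between-driver
alignment; refitting per surrogate would conflate it with coefficient
shrinkage. (`zero_beta=True` instead drops the driver outright, the
"coefficient set to zero" variant.) Synchrony-preserving surrogates
remove only cross-driver alignment; independent-phase surrogates also
remove the driver's own synchrony. The one-sided rank p compares the
observed band-mean model synchrony with the surrogate distribution.

## Synthetic test bed

`two_driver_scenario(phi, seed)` generates the fully specified
construction used for validation: `N = 26`, `T = 60`, angular
frequency `w = 2π/20`. Each variable mixes a synchronous component and
independent standard-normal local noise with weights `√(1/4)` and
`√(3/4)` (variance ratio 1:3):

- driver `α`: synchronous part `√2 sin(wt)`;
- driver `β`: synchronous part `√2 cos(wt − φπ)`, generated from
  `t = −5` so its 5-year-lagged values exist from the first year
  (pre-sample local noise freshly drawn — any stationary choice is
  equivalent);
- populations: `γ⁽¹⁾` driven by `−α`, `γ⁽²⁾` by `−β(t−5)` (a quarter
  of the 20-year cycle), `γ⁽³⁾` by `−(α + β(t−5))/f` with
  `f = √(2 + cos(φπ)/2)` normalizing the joint influence to unit
  variance, so the three populations receive equally strong forcing.

At `φ = 0` the two influences are exactly in phase and reinforce; at
`φ = 1` they oppose; quarter-cycle-shifted sinusoids are uncorrelated,
so the jointly driven population's synchrony crosses the singly driven
level at `φ = 0.5`. One master seed spawns independent substreams per
noise field, preventing accidental cross-correlation; identical seeds
reproduce scenarios bitwise.

`ar1_moran` provides the classical Moran-theorem limit (population
cross-correlation equals driver cross-correlation for shared AR(1)
dynamics; burn-in 100 steps), and `sync_panel` generalizes the
construction (arbitrary period, synchronous-variance fraction, lag,
phase) for property tests.

What the test bed does *not* emulate: sampling noise and irregular
effort, missing data, spatial gradients or distance-decaying synchrony,
non-Gaussian marginals, broadband or nonstationary oscillations, and
dispersal coupling. Passing tests establish that the estimators
recover known structure under clean, stationary, Gaussian conditions
at realistic panel sizes — not that every real-data inference at these
sample sizes is equally well powered; in particular, drop tests for
mutually redundant drivers lose power when the analysis band is
restricted to the shared timescale alone (the full long band restores
it).

## Problem sizes and numerical conventions

- Validation scales: the crossover sweep uses 11 phase offsets × 50
  realisations; peak-timescale and lag recovery use 20 realisations;
  type-I calibration uses 200 replicates × 199 surrogates on 10 × 60
  panels; the AR(1) Moran check uses `T = 5000`. Unit tests exercise
  the same properties at smaller Monte-Carlo sizes.
- Bands are closed intervals on the grid, aggregated with equal weight
  per grid point; the default short/long split at 4 years reflects the
  boundary between year-to-year persistence and anti-persistence in
  annual data. No default grid point falls on 4.0.
- Surrogate counts default to 1000; p-values use the `+1` rank rule.
- Tolerances: mean/variance contracts to `1e-8`; linear identities
  (mean-field linearity, attribution conservation) to `1e-10`/`1e-8`;
  phasor magnitudes to `1e-10`. Zero transform cells map to zero
  phasors; all-zero locations are an error in power normalization.
- Reproducibility: every stochastic routine takes a seed; scenario
  generation and surrogate streams derive substreams via
  `SeedSequence.spawn`.

## Known limitations

- The strict 1% COI criterion flags the entire time axis at long
  timescales for short records; summaries there rest on full-axis
  averages of attenuated cells (conservative, but long-timescale
  synchrony near `T/2` is underestimated rather than precisely
  calibrated).
- Pointwise WPMF thresholds carry no multiple-testing control.
- Subset selection is exhaustive and capped at five predictors; no
  stepwise or regularized search is provided.
- Attribution fractions are band aggregates of the observed response —
  with near-zero observed synchrony in a band (strongly counteracting
  drivers) the individual fractions are large and unstable even though
  their sum is well behaved.
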