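"""Partitioning observed synchrony across drivers and their interaction.

Applies the wavelet Moran theorem and the synchrony attribution theorem
to the jointly driven population: how much of its band synchrony do the
two drivers explain, how does that split between them, and how much
comes from their mutual reinforcement? Then checks the interaction
empirically by randomizing one driver with synchrony-preserving
surrogates (its own synchrony survives; its alignment with the other
driver does not).
"""

from moranwave import (
    SurrogateSpec,
    WaveletConfig,
    attribute_synchrony,
    fit_wlm_panels,
    fraction_explained,
    interaction_randomization,
    standardize,
    two_driver_scenario,
)

cfg = WaveletConfig()
band = (4.0, 30.0)

for phi in (0.0, 1.0):
    sc = two_driver_scenario(phi=phi, seed=4)
    w0_panel = standardize(sc.gamma3)
    model = fit_wlm_panels(
        w0_panel,
        [standardize(sc.alpha), standardize(sc.beta_lagged)],
        band=band, config=cfg, predictor_ids=("alpha", "beta_lagged"),
    )
    w0 = cfg.power(w0_panel)
    frac = fraction_explained(model, w0, band)
    part = attribute_synchrony(model, w0, band)
    print(f"phi = {phi}: fraction of band synchrony explained = {frac:.3f}")
    for name, value in part.fraction_per_predictor.items():
        print(f"  {name}: {value:+.3f}")
    print(f"  interactions: {part.fraction_interactions:+.3f} "
          f"({'reinforcing' if part.fraction_interactions > 0 else 'counteracting'})")

sc = two_driver_scenario(phi=0.0, seed=4)
model = fit_wlm_panels(
    standardize(sc.gamma3),
    [standardize(sc.alpha), standardize(sc.beta_lagged)],
    band=band, config=cfg, predictor_ids=("alpha", "beta_lagged"),
)
result = interaction_randomization(
    model, 0, SurrogateSpec("fourier_synchrony_preserving", 500, seed=4), band
)
ratio = result.surrogate_band_means.mean() / result.observed_band_mean
print(f"\nrandomizing away driver alignment: surrogate model synchrony is "
      f"{100 * ratio:.0f}% of observed (one-sided p = {result.pvalue:.4f})")
print("A ratio below 100% with small p shows the drivers' mutual alignment "
      "itself contributes synchrony beyond their separate effects.")
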