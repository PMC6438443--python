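"""Complex wavelet regression and model selection against a noise decoy.

Fits the jointly driven population gamma3 on its two true drivers plus a
pure-noise decoy, and lets the selection procedure (surrogate drop tests
+ leave-one-location-out cross validation) decide which predictors stay.
The complex coefficients encode each driver's phase relationship.
"""

import numpy as np

from moranwave import (
    SpatioTemporalSeries,
    SurrogateSpec,
    WaveletConfig,
    fit_wlm_panels,
    select_models,
    standardize,
    two_driver_scenario,
)

cfg = WaveletConfig()
band = (4.0, 30.0)
sc = two_driver_scenario(phi=0.0, seed=3)
rng = np.random.default_rng(3)
decoy = SpatioTemporalSeries(
    rng.standard_normal((26, 60)), tuple(f"l{i}" for i in range(26)), np.arange(60)
)

model = fit_wlm_panels(
    standardize(sc.gamma3),
    [standardize(sc.alpha), standardize(sc.beta_lagged)],
    band=band, config=cfg, predictor_ids=("alpha", "beta_lagged"),
)
j = int(np.argmin(np.abs(model.timescales - 20)))
for k, pid in enumerate(model.predictor_ids):
    beta = model.betas[k, j]
    print(f"beta_{pid}(20y) = {np.abs(beta):.3f} * exp({np.angle(beta):+.2f}i) "
          "(phase ~pi: inverse influence)")

ranked = select_models(
    standardize(sc.gamma3),
    {
        "alpha": standardize(sc.alpha),
        "beta_lagged": standardize(sc.beta_lagged),
        "decoy": standardize(decoy),
    },
    band, cfg, max_k=3, alpha=0.05,
    spec=SurrogateSpec("fourier_synchrony_preserving", 200, seed=3),
)
print(f"{len(ranked)} predictor subset(s) survived the drop tests; top model:")
top = ranked[0]
print(f"  predictors {top.predictor_ids}, leave-one-out score {top.loo_score:.3f}, "
      f"drop p-values {tuple(round(p, 4) for p in top.drop_pvalues)}")
print("The decoy is excluded: removing it never significantly hurts the model.")
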