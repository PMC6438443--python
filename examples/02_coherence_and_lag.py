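"""Spatial coherence detects a phase-lagged driver that correlation misses.

The population gamma2 responds to the climatic driver beta inverted and
delayed by 5 years — a quarter of the 20-year cycle. Plain correlation
between the two panels is near zero; the timescale-specific coherence is
strong, and its cross-phase recovers the lag.
"""

import numpy as np

from moranwave import (
    SurrogateSpec,
    WaveletConfig,
    coherence_band_test,
    spatial_coherence,
    standardize,
    two_driver_scenario,
)

cfg = WaveletConfig()
sc = two_driver_scenario(phi=0.0, seed=2)
response = standardize(sc.gamma2)
driver = standardize(sc.beta)

r = np.corrcoef(response.values.ravel(), driver.values.ravel())[0, 1]
print(f"pooled correlation between population and driver: {r:+.3f} (tiny)")

profile = spatial_coherence(cfg.power(response), cfg.power(driver))
j = int(np.argmin(np.abs(profile.timescales - 20)))
sigma = profile.timescales[j]
theta = profile.cross_phase[j]
lag = ((np.pi - theta + np.pi) % (2 * np.pi) - np.pi) / (2 * np.pi) * sigma
print(f"coherence at {sigma:.1f} years: {profile.pi[j]:.3f}, cross-phase {theta:+.3f} rad")
print(f"after removing the construction's sign inversion, implied lag: {lag:.2f} years "
      f"(construction: 5)")

observed, p, _ = coherence_band_test(
    response, driver, band=(4.0, 30.0),
    spec=SurrogateSpec("fourier_synchrony_preserving", 500, seed=2), config=cfg,
)
print(f"band-mean coherence {observed:.3f}; surrogate p = {p:.4f} "
      "(synchrony-preserving surrogates destroy only the cross-variable relationship)")
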