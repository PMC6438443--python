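"""Wavelet mean fields of a partially synchronous driver.

Generates the two-driver construction (26 locations, 60 years: a shared
20-year sinusoid carrying 1/4 of each location's variance, the rest
independent noise), computes the wavelet mean field (WMF) and phasor
mean field (WPMF), and locates the timescale of peak synchrony.
"""

import numpy as np

from moranwave import (
    WaveletConfig,
    standardize,
    two_driver_scenario,
    wmf,
    wpmf,
    wpmf_thresholds,
)

cfg = WaveletConfig()
scenario = two_driver_scenario(phi=0.0, seed=1)
driver = standardize(scenario.alpha)

surface = wmf(cfg.power(driver))
peak = surface.timescales[np.argmax(surface.msq)]
print(f"WMF mean squared synchrony peaks at {peak:.2f} years "
      f"(construction period: 20 years)")

phase_surface = wpmf(cfg.phasor(driver))
threshold = wpmf_thresholds(driver.n_locations, n_draws=20_000, seed=1).threshold(0.05)
j = int(np.argmin(np.abs(phase_surface.timescales - 20)))
frac = np.mean(np.abs(phase_surface.values[:, j]) > threshold)
print(f"WPMF at the 20-year timescale exceeds the 5% significance threshold "
      f"({threshold:.3f}) at {100 * frac:.0f}% of time points")
print("High values mean the 26 locations oscillate in phase there — "
      "the shared sinusoid is detected; independent noise would sit below the threshold.")
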