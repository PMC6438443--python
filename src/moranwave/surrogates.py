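"""Fourier surrogates for significance testing of timescale-specific statistics.

Phase randomization produces surrogate panels sharing each original
series' periodogram (hence autocorrelation) while scrambling everything
the null hypothesis should destroy:

* ``fourier_independent`` — independent phase draws per location. Each
  location keeps its own spectrum but spatial synchrony is destroyed.
* ``fourier_synchrony_preserving`` — one shared phase draw applied to all
  locations of the variable. All within-variable cross-spectra (and so
  the variable's own synchrony structure) are preserved exactly, while
  relationships with any *other* variable are destroyed. These are the
  "spatially synchronous surrogates" used to test whether a predictor's
  alignment with other variables matters.

Zero-frequency and (for even length) Nyquist coefficients are left
untouched, so surrogates keep each location's sample mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import SpatioTemporalSeries

__all__ = ["SurrogateSpec", "fourier_surrogates", "surrogate_stream"]

_KINDS = ("fourier_independent", "fourier_synchrony_preserving")


@dataclass(frozen=True)
class SurrogateSpec:
    """How many surrogates of which kind, and the seed that drives them."""

    kind: str
    count: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown surrogate kind {self.kind!r}; expected one of {_KINDS}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1; got {self.count}")


def _randomized(values: np.ndarray, rng: np.random.Generator, shared: bool) -> np.ndarray:
    n, t = values.shape
    spectrum = np.fft.rfft(values, axis=1)
    n_freq = spectrum.shape[1]
    # indices of strictly positive, non-Nyquist frequencies
    top = n_freq - 1 if t % 2 == 0 else n_freq
    n_rand = top - 1
    if shared:
        phases = np.broadcast_to(rng.uniform(0.0, 2 * np.pi, size=n_rand), (n, n_rand))
    else:
        phases = rng.uniform(0.0, 2 * np.pi, size=(n, n_rand))
    spectrum = spectrum.copy()
    spectrum[:, 1:top] *= np.exp(1j * phases)
    return np.fft.irfft(spectrum, n=t, axis=1)


def fourier_surrogates(
    series: SpatioTemporalSeries, spec: SurrogateSpec
) -> list[SpatioTemporalSeries]:
    """Generate ``spec.count`` surrogate panels of a cleaned panel."""
    if series.n_times < 4:
        raise ValueError("need at least 4 time steps for Fourier surrogates")
    rng = np.random.default_rng(spec.seed)
    shared = spec.kind == "fourier_synchrony_preserving"
    return [series.with_values(_randomized(series.values, rng, shared)) for _ in range(spec.count)]


def surrogate_stream(series: SpatioTemporalSeries, spec: SurrogateSpec):
    """Yield surrogates one at a time (same draws as :func:`fourier_surrogates`)."""
    if series.n_times < 4:
        raise ValueError("need at least 4 time steps for Fourier surrogates")
    rng = np.random.default_rng(spec.seed)
    shared = spec.kind == "fourier_synchrony_preserving"
    for _ in range(spec.count):
        yield series.with_values(_randomized(series.values, rng, shared))
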