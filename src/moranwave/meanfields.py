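"""Wavelet mean fields: across-location averages of normalized transforms.

The wavelet mean field (WMF) averages power-normalized transforms over
locations; its magnitude surface ``|r_sigma(t)|`` displays spatial
synchrony as a function of time and timescale — aligned oscillations add
constructively, independent ones cancel. The wavelet phasor mean field
(WPMF) averages unit-magnitude transforms instead, quantifying pure phase
synchrony; its magnitude lies in [0, 1] and admits a simple significance
test against the null of independent uniformly distributed phases.

The time average of squared magnitude at a timescale,
``{|r_sigma(t)|}_t``, is the *mean squared synchrony*; aggregated over a
timescale band it is the quantity the Moran and attribution theorems
partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .wavelets import NormalizedTransformSet, band_indices

__all__ = [
    "MeanFieldSurface",
    "SignificanceSurface",
    "wmf",
    "wpmf",
    "wpmf_thresholds",
    "mean_squared_synchrony",
]


@dataclass(frozen=True)
class MeanFieldSurface:
    """A complex ``(T, S)`` mean-field surface with per-timescale summary.

    ``msq[j]`` is the mean of ``|values[t, j]|**2`` over the included time
    points at timescale ``j`` (non-edge times where available).
    """

    values: np.ndarray
    kind: str
    timescales: np.ndarray
    msq: np.ndarray
    include_mask: np.ndarray
    years: np.ndarray | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass(frozen=True)
class SignificanceSurface:
    """Monte-Carlo WPMF magnitude thresholds under the uniform-phase null."""

    levels: tuple[float, ...]
    thresholds: np.ndarray
    n_locations: int
    n_draws: int
    seed: int | None

    def threshold(self, level: float) -> float:
        for lv, th in zip(self.levels, self.thresholds):
            if abs(lv - level) < 1e-12:
                return float(th)
        raise KeyError(f"level {level} not among {self.levels}")


def _mean_field(normalized: NormalizedTransformSet, expected: str, kind: str) -> MeanFieldSurface:
    if normalized.normalization != expected:
        raise ValueError(
            f"{kind} requires {expected}-normalized transforms; got {normalized.normalization!r}"
        )
    values = normalized.coefficients.mean(axis=0)
    # msq averages over the full time axis at every timescale: a uniform
    # cell set keeps per-timescale summaries comparable across the grid
    # (edge cells are amplitude-attenuated, not inflated, under the
    # truncated-convolution transform, so they cannot fake synchrony).
    include = np.ones(values.shape, dtype=bool)
    sq = np.abs(values) ** 2
    msq = np.array([sq[include[:, j], j].mean() for j in range(sq.shape[1])])
    return MeanFieldSurface(
        values=values,
        kind=kind,
        timescales=normalized.timescales,
        msq=msq,
        include_mask=include,
        years=normalized.years,
    )


def wmf(normalized: NormalizedTransformSet) -> MeanFieldSurface:
    """Wavelet mean field of power-normalized transforms."""
    return _mean_field(normalized, "power", "wmf")


def wpmf(normalized: NormalizedTransformSet) -> MeanFieldSurface:
    """Wavelet phasor mean field of phasor-normalized transforms."""
    return _mean_field(normalized, "phasor", "wpmf")


def wpmf_thresholds(
    n_locations: int,
    levels: tuple[float, ...] = (0.1, 0.05, 0.01, 0.001),
    n_draws: int = 10_000,
    seed: int | None = None,
) -> SignificanceSurface:
    """Pointwise WPMF magnitude thresholds by Monte Carlo.

    Under the null of no phase association, each cell of the WPMF is the
    mean of ``N`` independent unit phasors with uniform phases; the
    threshold at level ``alpha`` is the ``1 - alpha`` quantile of its
    magnitude. For large ``N`` this approaches the Rayleigh limit
    ``sqrt(-log(alpha)/N)``.
    """
    if n_locations < 2:
        raise ValueError(f"need at least 2 locations; got {n_locations}")
    levels = tuple(levels)
    if not all(0 < a < 1 for a in levels):
        raise ValueError(f"levels must lie in (0, 1); got {levels}")
    if n_draws < 1000:
        warnings.warn(f"n_draws = {n_draws} < 1000: thresholds will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    mags = np.empty(n_draws)
    chunk = max(1, min(n_draws, int(2e6) // max(n_locations, 1)))
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        phases = rng.uniform(0.0, 2 * np.pi, size=(m, n_locations))
        mags[done : done + m] = np.abs(np.exp(1j * phases).mean(axis=1))
        done += m
    thresholds = np.array([np.quantile(mags, 1 - a) for a in levels])
    return SignificanceSurface(levels, thresholds, n_locations, n_draws, seed)


def mean_squared_synchrony(surface: MeanFieldSurface, band: tuple[float, float]) -> float:
    """Band-aggregated mean squared synchrony (equal weight per grid point)."""
    idx = band_indices(surface.timescales, band)
    return float(surface.msq[idx].mean())
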