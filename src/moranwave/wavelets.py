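"""Complex Morlet wavelet transforms on a geometric timescale grid.

The transform of a time series :math:`x(t)` at timescale :math:`\\sigma`
(in years) and time :math:`t` is

.. math::

    W_\\sigma(t) = \\sum_u x(u)\\,\\overline{\\psi_{\\sigma,t}(u)},
    \\qquad
    \\psi_{\\sigma,t}(u) = \\sigma^{-1/2}\\pi^{-1/4}
        e^{i 2\\pi f_0 (u-t)/\\sigma} e^{-(u-t)^2/(2\\sigma^2)},

with the kernel truncated at ``|u - t| > 4 sigma``. With the default
central frequency ``f0 = 1`` the magnitude response to a pure sinusoid of
period ``P`` peaks at the grid timescale nearest ``P``, so timescale reads
directly as oscillation period. The transform is computed by direct
(truncated) convolution, which keeps edge behaviour exact and easy to
reason about at the series lengths this package targets (tens of years).

Edge-affected cells are flagged in a cone-of-influence mask rather than
deleted: a cell is flagged when the kernel, clipped by the series
boundary, retains less than 99% of its untruncated L2 norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import SpatioTemporalSeries

__all__ = [
    "WaveletConfig",
    "WaveletTransformSet",
    "NormalizedTransformSet",
    "geometric_timescales",
    "morlet_transform",
    "normalize",
    "band_indices",
]

_KERNEL_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def geometric_timescales(
    n_times: int,
    sigma_min: float = 2.0,
    sigma_max: float | None = None,
    spacing: float = 1.05,
) -> np.ndarray:
    """Geometric grid ``sigma_min, sigma_min*spacing, ...`` up to ``sigma_max``.

    ``sigma_max`` defaults to ``n_times / 2``; the grid stops at the
    largest point not exceeding it (annual data resolve nothing shorter
    than 2 years nor longer than half the record).
    """
    if sigma_max is None:
        sigma_max = n_times / 2
    if not sigma_min < sigma_max:
        raise ValueError(f"need sigma_min < sigma_max; got {sigma_min}, {sigma_max}")
    if sigma_min < 2 - 1e-9 or sigma_max > n_times / 2 + 1e-9:
        raise ValueError(
            f"timescale bounds [{sigma_min}, {sigma_max}] outside [2, T/2] = [2, {n_times / 2}]"
        )
    if spacing <= 1:
        raise ValueError(f"spacing must exceed 1; got {spacing}")
    n_scales = int(np.floor(np.log(sigma_max / sigma_min) / np.log(spacing) + 1e-9)) + 1
    return sigma_min * spacing ** np.arange(n_scales)


@dataclass(frozen=True)
class WaveletConfig:
    """Transform parameters: timescale grid bounds, spacing, and f0."""

    sigma_min: float = 2.0
    sigma_max: float | None = None
    spacing: float = 1.05
    f0: float = 1.0

    def timescales(self, n_times: int) -> np.ndarray:
        return geometric_timescales(n_times, self.sigma_min, self.sigma_max, self.spacing)

    def transform(self, series: SpatioTemporalSeries) -> "WaveletTransformSet":
        return morlet_transform(series, self.sigma_min, self.sigma_max, self.spacing, self.f0)

    def power(self, series: SpatioTemporalSeries) -> "NormalizedTransformSet":
        return normalize(self.transform(series), "power")

    def phasor(self, series: SpatioTemporalSeries) -> "NormalizedTransformSet":
        return normalize(self.transform(series), "phasor")


def _kernels(n_times: int, timescales: np.ndarray, f0: float) -> tuple[np.ndarray, np.ndarray]:
    """Conjugated kernel matrices ``K[s, u, t]`` and the (T, S) COI mask."""
    key = (n_times, len(timescales), round(float(timescales[0]), 12), round(float(timescales[-1]), 12), round(f0, 12))
    hit = _KERNEL_CACHE.get(key)
    if hit is not None:
        return hit
    u = np.arange(n_times)[:, None]
    t = np.arange(n_times)[None, :]
    d = (u - t).astype(float)
    n_scales = len(timescales)
    kernels = np.empty((n_scales, n_times, n_times), dtype=complex)
    coi = np.empty((n_times, n_scales), dtype=bool)
    for j, sigma in enumerate(timescales):
        envelope = np.exp(-(d**2) / (2 * sigma**2))
        k = sigma**-0.5 * np.pi**-0.25 * np.exp(-2j * np.pi * f0 * d / sigma) * envelope
        k[np.abs(d) > 4 * sigma] = 0.0
        kernels[j] = k
        # L2-norm retention of the clipped+truncated kernel vs the
        # untruncated (infinite-support) kernel, per output time t.
        span = int(np.ceil(8 * sigma))
        dd = np.arange(-span, span + 1, dtype=float)
        full_sq = np.exp(-(dd**2) / sigma**2).sum() * sigma**-1 * np.pi**-0.5
        kept_sq = (np.abs(k) ** 2).sum(axis=0)
        coi[:, j] = np.sqrt(kept_sq / full_sq) < 0.99
    _KERNEL_CACHE[key] = (kernels, coi)
    return kernels, coi


def _include_mask(coi_ts: np.ndarray) -> np.ndarray:
    """Per-timescale analysis mask over time points.

    Non-edge (non-COI) times where any exist at a timescale; at timescales
    whose non-COI set is empty (long periods relative to the record) the
    whole time axis is retained, so that statistics remain defined across
    the full grid.
    """
    include = ~coi_ts
    empty = ~include.any(axis=0)
    include[:, empty] = True
    return include


@dataclass(frozen=True)
class WaveletTransformSet:
    """Raw complex transforms ``W_{n,sigma}(t)``, shape ``(N, T, S)``."""

    coefficients: np.ndarray
    timescales: np.ndarray
    central_frequency: float
    coi_mask: np.ndarray
    location_ids: tuple[str, ...] = ()
    years: np.ndarray | None = None

    def __post_init__(self) -> None:
        ratios = self.timescales[1:] / self.timescales[:-1]
        if len(ratios) and np.ptp(ratios) > 1e-10:
            raise ValueError("timescales must form a geometric grid")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite wavelet coefficients")

    @property
    def include_mask(self) -> np.ndarray:
        """(T, S) boolean mask of time points used by summary statistics."""
        return _include_mask(self.coi_mask[0])


@dataclass(frozen=True)
class NormalizedTransformSet:
    """Transforms rescaled for mean-field / coherence analysis.

    ``phasor``: every nonzero cell has unit magnitude (phase only).
    ``power``: each location divided by the square root of its mean squared
    magnitude over all cells, so per-location mean power is 1 while the
    relative distribution of power across time and timescale is kept.
    """

    coefficients: np.ndarray
    normalization: str
    timescales: np.ndarray
    coi_mask: np.ndarray
    location_ids: tuple[str, ...] = ()
    years: np.ndarray | None = None

    @property
    def include_mask(self) -> np.ndarray:
        return _include_mask(self.coi_mask[0])

    @property
    def n_locations(self) -> int:
        return self.coefficients.shape[0]


def morlet_transform(
    series: SpatioTemporalSeries,
    sigma_min: float = 2.0,
    sigma_max: float | None = None,
    spacing: float = 1.05,
    f0: float = 1.0,
) -> WaveletTransformSet:
    """Transform every location of a cleaned (zero-mean) panel.

    Raises if any location mean is materially nonzero: transforms of
    uncentred data leak the mean into long timescales.
    """
    if f0 <= 0:
        raise ValueError(f"central frequency f0 must be positive; got {f0}")
    means = series.values.mean(axis=1)
    scale = max(series.values.std(), 1e-12)
    if np.abs(means).max() > 1e-6 * scale:
        raise ValueError(
            "series must be cleaned (per-location mean 0) before transforming; "
            "see preprocess.boxcox_clean / preprocess.standardize"
        )
    timescales = geometric_timescales(series.n_times, sigma_min, sigma_max, spacing)
    kernels, coi_ts = _kernels(series.n_times, timescales, f0)
    # W[n, t, s] = sum_u x[n, u] * K[s, u, t]
    coeffs = np.tensordot(series.values, kernels, axes=([1], [1])).transpose(0, 2, 1)
    coi = np.broadcast_to(coi_ts, (series.n_locations,) + coi_ts.shape)
    return WaveletTransformSet(
        coefficients=np.ascontiguousarray(coeffs),
        timescales=timescales,
        central_frequency=f0,
        coi_mask=coi,
        location_ids=series.location_ids,
        years=series.years,
    )


def normalize(transforms: WaveletTransformSet, method: str) -> NormalizedTransformSet:
    """Rescale transforms: ``phasor`` (unit magnitude) or ``power``."""
    w = transforms.coefficients
    if method == "phasor":
        mag = np.abs(w)
        out = np.divide(w, mag, out=np.zeros_like(w), where=mag > 0)
    elif method == "power":
        mean_power = np.mean(np.abs(w) ** 2, axis=(1, 2))
        if np.any(mean_power == 0):
            idx = int(np.argmin(mean_power))
            label = transforms.location_ids[idx] if transforms.location_ids else str(idx)
            raise ValueError(f"all-zero transform at location {label!r}: cannot power-normalize")
        out = w / np.sqrt(mean_power)[:, None, None]
    else:
        raise ValueError(f"unknown normalization {method!r}; expected 'phasor' or 'power'")
    return NormalizedTransformSet(
        coefficients=out,
        normalization=method,
        timescales=transforms.timescales,
        coi_mask=transforms.coi_mask,
        location_ids=transforms.location_ids,
        years=transforms.years,
    )


def band_indices(timescales: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Indices of grid timescales inside the closed interval ``band``."""
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band {band} is empty")
    idx = np.nonzero((timescales >= lo) & (timescales <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"band {band} contains no grid timescales")
    return idx
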