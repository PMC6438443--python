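"""Synthetic spatiotemporal scenarios with known synchrony structure.

Three generators:

* :func:`two_driver_scenario` — the fully specified two-driver
  construction used throughout the package's validation: 26 locations,
  60 years, two partially synchronous environmental drivers sharing a
  20-year periodicity (a sine-based driver ``alpha`` and a phase-shifted
  cosine-based driver ``beta``), and three driven population variables
  responding to one driver, to the other with a 5-year lag, or to both.
  Sweeping the phase parameter ``phi`` moves driver interactions from
  reinforcing to cancelling, with the crossover at ``phi = 0.5``.
* :func:`ar1_moran` — the classic Moran-theorem setting: AR(1)
  populations forced by spatially correlated Gaussian drivers, where the
  between-location population correlation converges to the driver
  correlation.
* :func:`sync_panel` — a generic synchronous-sinusoid-plus-noise panel
  for property tests.

All generators are reproducible: one master seed spawns independent
substreams per noise field, so no two noise fields are accidentally
correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import SpatioTemporalSeries

__all__ = ["TwoDriverScenario", "AR1Scenario", "two_driver_scenario", "ar1_moran", "sync_panel"]

PERIOD = 20.0
LAG = 5
_A_SYNC = np.sqrt(1 / 4)  # synchronous-component weight: 1/4 of variance
_A_LOCAL = np.sqrt(3 / 4)  # local-noise weight: 3/4 of variance


@dataclass(frozen=True)
class TwoDriverScenario:
    """One realisation of the two-driver construction.

    ``gamma1`` responds to ``-alpha`` (antiphase), ``gamma2`` to
    ``-beta`` lagged 5 years (a quarter of the 20-year cycle), ``gamma3``
    to the normalized sum of both influences. ``beta_lagged`` holds
    ``beta(n, t - 5)`` on the same year axis, i.e. the predictor a
    regression of ``gamma2`` or ``gamma3`` on the climatic driver needs.
    ``f = sqrt(2 + cos(phi * pi) / 2)`` normalizes the combined influence
    to unit variance through time.
    """

    alpha: SpatioTemporalSeries
    beta: SpatioTemporalSeries
    beta_lagged: SpatioTemporalSeries
    gamma1: SpatioTemporalSeries
    gamma2: SpatioTemporalSeries
    gamma3: SpatioTemporalSeries
    phi: float
    f: float
    w: float
    seed: int | None

    @property
    def panels(self) -> dict[str, SpatioTemporalSeries]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "beta_lagged": self.beta_lagged,
            "gamma1": self.gamma1,
            "gamma2": self.gamma2,
            "gamma3": self.gamma3,
        }


@dataclass(frozen=True)
class AR1Scenario:
    """AR(1) populations with their Gaussian driver fields."""

    gamma: SpatioTemporalSeries
    alpha: SpatioTemporalSeries
    beta: SpatioTemporalSeries
    ar_coefficient: float
    weight_alpha: float
    weight_beta: float
    seed: int | None


def two_driver_scenario(
    phi: float,
    seed: int | None = None,
    n_locations: int = 26,
    n_times: int = 60,
) -> TwoDriverScenario:
    """Generate one seeded realisation of the two-driver construction.

    With ``w = 2 pi / 20`` and weights ``sqrt(1/4)`` / ``sqrt(3/4)`` on
    synchronous and local components:

    * ``alpha = sqrt(1/4) * sqrt(2) sin(w t) + sqrt(3/4) * noise``
    * ``beta  = sqrt(1/4) * sqrt(2) cos(w t - phi pi) + sqrt(3/4) * noise``
    * ``gamma1 = sqrt(1/4) * (-alpha) + sqrt(3/4) * noise``
    * ``gamma2 = sqrt(1/4) * (-beta(t - 5)) + sqrt(3/4) * noise``
    * ``gamma3 = sqrt(1/4) * (-(alpha + beta(t - 5)) / f) + sqrt(3/4) * noise``

    so every variable mixes a synchronous component with independent
    local noise in combination ratio 1:3, and the combined influence on
    ``gamma3`` has the same variance through time as the single-driver
    influences. ``beta`` is generated from ``t = -5`` so the lag is
    defined from the first year.
    """
    if not 0 <= phi <= 1:
        raise ValueError(f"phi must lie in [0, 1]; got {phi}")
    w = 2 * np.pi / PERIOD
    f = float(np.sqrt(2 + 0.5 * np.cos(phi * np.pi)))
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(5)]
    rng_alpha, rng_beta, rng_g1, rng_g2, rng_g3 = streams

    t = np.arange(n_times, dtype=float)
    t_ext = np.arange(-LAG, n_times, dtype=float)  # beta from t = -5

    alpha = _A_SYNC * np.sqrt(2) * np.sin(w * t) + _A_LOCAL * rng_alpha.standard_normal(
        (n_locations, n_times)
    )
    beta_ext = _A_SYNC * np.sqrt(2) * np.cos(w * t_ext - phi * np.pi) + _A_LOCAL * (
        rng_beta.standard_normal((n_locations, n_times + LAG))
    )
    beta = beta_ext[:, LAG:]
    beta_lagged = beta_ext[:, :n_times]  # beta(n, t - 5) for t = 0..T-1

    def driven(sync: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return _A_SYNC * sync + _A_LOCAL * rng.standard_normal((n_locations, n_times))

    gamma1 = driven(-alpha, rng_g1)
    gamma2 = driven(-beta_lagged, rng_g2)
    gamma3 = driven(-(alpha + beta_lagged) / f, rng_g3)

    ids = tuple(f"loc{i:02d}" for i in range(n_locations))
    years = np.arange(n_times)

    def panel(values: np.ndarray) -> SpatioTemporalSeries:
        return SpatioTemporalSeries(values, ids, years)

    return TwoDriverScenario(
        alpha=panel(alpha),
        beta=panel(beta),
        beta_lagged=panel(beta_lagged),
        gamma1=panel(gamma1),
        gamma2=panel(gamma2),
        gamma3=panel(gamma3),
        phi=float(phi),
        f=f,
        w=float(w),
        seed=seed,
    )


def ar1_moran(
    n_locations: int = 2,
    n_times: int = 5000,
    a: float = 0.5,
    weight_alpha: float = 1.0,
    weight_beta: float = 0.0,
    rho_alpha: float = 0.0,
    rho_beta: float = 0.0,
    rho_drivers: float = 0.0,
    seed: int | None = None,
    burn_in: int = 100,
) -> AR1Scenario:
    """AR(1) populations forced by correlated Gaussian driver fields.

    ``gamma(n, t) = a gamma(n, t-1) + eps(n, t)`` with
    ``eps = weight_alpha * alpha + weight_beta * beta``. Each driver is an
    equicorrelated Gaussian field across locations (correlation
    ``rho_alpha`` / ``rho_beta``), built from a common component plus
    location-specific components; ``rho_drivers`` correlates the two
    drivers' common components. Because both locations share the same
    AR filter, the between-location population correlation equals the
    between-location driver correlation (the Moran theorem), which the
    package's estimators should recover at large ``n_times``.
    """
    if not abs(a) < 1:
        raise ValueError(f"AR coefficient must satisfy |a| < 1 for stationarity; got {a}")
    for name, rho in (("rho_alpha", rho_alpha), ("rho_beta", rho_beta), ("rho_drivers", rho_drivers)):
        if not 0 <= rho <= 1:
            raise ValueError(f"{name} must lie in [0, 1]; got {rho}")
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)]
    rng_ca, rng_la, rng_cb, rng_lb = streams

    total = burn_in + n_times

    def field(rho: float, common: np.ndarray, rng_local: np.random.Generator) -> np.ndarray:
        local = rng_local.standard_normal((n_locations, total))
        return np.sqrt(rho) * common[None, :] + np.sqrt(1 - rho) * local

    common_a = rng_ca.standard_normal(total)
    common_b = rho_drivers * common_a + np.sqrt(1 - rho_drivers**2) * rng_cb.standard_normal(total)
    alpha = field(rho_alpha, common_a, rng_la)
    beta = field(rho_beta, common_b, rng_lb)

    eps = weight_alpha * alpha + weight_beta * beta
    gamma = np.empty_like(eps)
    gamma[:, 0] = eps[:, 0]
    for t in range(1, total):
        gamma[:, t] = a * gamma[:, t - 1] + eps[:, t]

    ids = tuple(f"loc{i:02d}" for i in range(n_locations))
    years = np.arange(n_times)
    sl = slice(burn_in, None)
    return AR1Scenario(
        gamma=SpatioTemporalSeries(gamma[:, sl], ids, years),
        alpha=SpatioTemporalSeries(alpha[:, sl], ids, years),
        beta=SpatioTemporalSeries(beta[:, sl], ids, years),
        ar_coefficient=a,
        weight_alpha=weight_alpha,
        weight_beta=weight_beta,
        seed=seed,
    )


def sync_panel(
    n_locations: int,
    n_times: int,
    period: float,
    sync_fraction: float,
    lag: float = 0.0,
    phase: float = 0.0,
    seed: int | None = None,
) -> SpatioTemporalSeries:
    """A shared sinusoid plus independent noise, at a chosen variance split.

    ``sqrt(sync_fraction) * sqrt(2) sin(2 pi (t - lag)/period + phase) +
    sqrt(1 - sync_fraction) * noise`` per location; ``sync_fraction``
    is the fraction of variance carried by the synchronous component.
    """
    if not 0 <= sync_fraction <= 1:
        raise ValueError(f"sync_fraction must lie in [0, 1]; got {sync_fraction}")
    if not 4 <= period <= n_times / 2:
        raise ValueError(f"period must lie in [4, T/2]; got {period}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_times, dtype=float)
    sync = np.sqrt(sync_fraction) * np.sqrt(2) * np.sin(2 * np.pi * (t - lag) / period + phase)
    noise = np.sqrt(1 - sync_fraction) * rng.standard_normal((n_locations, n_times))
    ids = tuple(f"loc{i:02d}" for i in range(n_locations))
    return SpatioTemporalSeries(sync[None, :] + noise, ids, np.arange(n_times))
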