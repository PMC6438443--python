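"""Wavelet Moran theorem and synchrony attribution.

If the only synchronizing influences on a response are the drivers in a
fitted wavelet model, then at each timescale the observed mean squared
synchrony approximately equals the model's mean squared synchrony times
the squared coherence between model and response:

.. math::

    \\{|r^{(0)}_\\sigma(t)|\\}_t \\approx
    \\{|r^{(h)}_\\sigma(t)|\\}_t \\, |\\Pi^{(0h)}_\\sigma|^2 ,

where :math:`r^{(h)}_\\sigma(t) = \\sum_k \\beta_k(\\sigma)
r^{(k)}_\\sigma(t)` is the model mean field. Unmodeled synchronizers turn
the approximation into an inequality (observed > predicted), so the right
side is the synchrony attributable to the modeled drivers, and the ratio
of band-aggregated sides is the fraction of synchrony explained.

Because the model mean field is a linear combination of driver mean
fields, its squared magnitude splits exactly into per-driver terms
``|beta_k|^2 |r_k|^2`` plus cross terms ``2 Re[beta_j conj(beta_k) r_j
conj(r_k)]``: the synchrony attribution theorem. Cross terms capture
interactions between drivers — reinforcement when drivers' synchronous
components are favourably phased, cancellation otherwise — and can be
negative. Interaction randomization probes the same effect empirically,
replacing one driver by surrogates that keep its own synchrony but break
its alignment with the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meanfields import MeanFieldSurface, wmf
from .surrogates import SurrogateSpec, surrogate_stream
from .wavelets import NormalizedTransformSet, band_indices
from .wlm import WaveletModel

__all__ = [
    "SynchronyPartition",
    "InteractionRandomization",
    "model_mean_field",
    "predicted_synchrony",
    "fraction_explained",
    "attribute_synchrony",
    "interaction_randomization",
]


@dataclass(frozen=True)
class SynchronyPartition:
    """Band fractions of observed synchrony attributed to each driver.

    ``fraction_per_predictor[k] + fraction_interactions == fraction_total``
    by construction; ``pairwise_terms[(j, k)]`` are the individual cross
    terms (possibly negative) making up the interaction fraction.
    """

    band: tuple[float, float]
    fraction_total: float
    fraction_per_predictor: dict[str, float]
    fraction_interactions: float
    pairwise_terms: dict[tuple[str, str], float]


@dataclass(frozen=True)
class InteractionRandomization:
    """Observed vs surrogate model-synchrony curves for one randomized driver."""

    mode: str
    predictor_id: str
    timescales: np.ndarray
    observed_msq: np.ndarray
    surrogate_mean_msq: np.ndarray
    observed_band_mean: float
    surrogate_band_means: np.ndarray
    pvalue: float


def _driver_mean_fields(model: WaveletModel) -> np.ndarray:
    """(K, T, S) mean fields of the model's predictor transforms."""
    return np.stack([p.coefficients.mean(axis=0) for p in model.predictors])


def _msq(values_sq: np.ndarray, include: np.ndarray) -> np.ndarray:
    return np.array([values_sq[include[:, j], j].mean() for j in range(values_sq.shape[1])])


def model_mean_field(model: WaveletModel) -> MeanFieldSurface:
    """Mean field ``r_h`` of the fitted model surface.

    Computed both as the location average of the fitted transforms and as
    ``sum_k beta_k r_k``; the two routes agree to linear-algebra roundoff
    (verified), and the first is returned.
    """
    direct = model.fitted.mean(axis=0)
    via_drivers = np.einsum("ks,kts->ts", model.betas, _driver_mean_fields(model))
    if not np.allclose(direct, via_drivers, atol=1e-10):
        raise AssertionError("model mean field linearity identity violated")
    # same uniform time-cell policy as meanfields: msq over the full axis
    include = np.ones(direct.shape, dtype=bool)
    return MeanFieldSurface(
        values=direct,
        kind="wmf",
        timescales=model.timescales.copy(),
        msq=_msq(np.abs(direct) ** 2, include),
        include_mask=include,
        years=model.response.years,
    )


def predicted_synchrony(model: WaveletModel, response: NormalizedTransformSet) -> MeanFieldSurface:
    """Surface ``|Pi_sigma| * |r_h(t)|``: synchrony the drivers would produce.

    Scaling the model mean field magnitude by the model-response
    coherence discounts model synchrony that is not actually transmitted
    to the response; the result is comparable cell-by-cell with the
    response's own mean field magnitude.
    """
    rh = model_mean_field(model)
    values = model.model_coherence[None, :] * np.abs(rh.values)
    return MeanFieldSurface(
        values=values,
        kind="predicted",
        timescales=model.timescales.copy(),
        msq=_msq(values**2, rh.include_mask),
        include_mask=rh.include_mask,
        years=model.response.years,
    )


def fraction_explained(
    model: WaveletModel, response: NormalizedTransformSet, band: tuple[float, float]
) -> float:
    """Band fraction of observed mean squared synchrony the model explains.

    ``sum_band |Pi|^2 msq_h / sum_band msq_0`` with equal weight per grid
    timescale; 1 when the response exactly equals the model fit, near 0
    for a response unrelated to the drivers.
    """
    idx = band_indices(model.timescales, band)
    msq0 = wmf(response).msq
    denom = float(msq0[idx].sum())
    if denom <= 0:
        raise ValueError(f"no observed synchrony in band {band}")
    msq_h = model_mean_field(model).msq
    num = float((model.model_coherence[idx] ** 2 * msq_h[idx]).sum())
    return num / denom


def attribute_synchrony(
    model: WaveletModel, response: NormalizedTransformSet, band: tuple[float, float]
) -> SynchronyPartition:
    """Partition the explained band synchrony across drivers and interactions.

    Expands ``msq_h`` exactly into per-driver and pairwise cross terms,
    scales every term by ``|Pi|^2`` and the observed-band denominator of
    :func:`fraction_explained`, so the components sum to the total.
    """
    idx = band_indices(model.timescales, band)
    include = model_mean_field(model).include_mask
    fields = _driver_mean_fields(model)
    betas = model.betas
    k_total = model.n_predictors

    msq0 = wmf(response).msq
    denom = float(msq0[idx].sum())
    if denom <= 0:
        raise ValueError(f"no observed synchrony in band {band}")
    pi_sq = model.model_coherence**2

    per_predictor: dict[str, float] = {}
    for k in range(k_total):
        term = np.abs(betas[k]) ** 2 * _msq(np.abs(fields[k]) ** 2, include)
        per_predictor[model.predictor_ids[k]] = float((pi_sq[idx] * term[idx]).sum()) / denom

    pairwise: dict[tuple[str, str], float] = {}
    for j in range(k_total):
        for k in range(j + 1, k_total):
            cross_tk = fields[j] * fields[k].conj()
            c_jk = np.array(
                [cross_tk[include[:, s], s].mean() for s in range(cross_tk.shape[1])]
            )
            term = 2 * np.real(betas[j] * betas[k].conj() * c_jk)
            pairwise[(model.predictor_ids[j], model.predictor_ids[k])] = (
                float((pi_sq[idx] * term[idx]).sum()) / denom
            )

    interactions = float(sum(pairwise.values()))
    total = float(sum(per_predictor.values()) + interactions)
    return SynchronyPartition(
        band=band,
        fraction_total=total,
        fraction_per_predictor=per_predictor,
        fraction_interactions=interactions,
        pairwise_terms=pairwise,
    )


def interaction_randomization(
    model: WaveletModel,
    k: int,
    spec: SurrogateSpec,
    band: tuple[float, float],
    mode: str = "synchrony_preserving",
    zero_beta: bool = False,
) -> InteractionRandomization:
    """How much model synchrony rests on driver ``k``'s alignment with the rest.

    For each surrogate of predictor ``k``'s time-domain panel the model
    mean field is rebuilt with the original coefficients (isolating the
    between-driver alignment effect rather than refitting) and its
    per-timescale mean squared synchrony recorded. ``synchrony_preserving``
    surrogates keep driver ``k``'s own synchrony but break cross-driver
    relationships; ``asynchronous`` surrogates break both. The one-sided
    rank p-value compares the observed band mean against the surrogate
    band means. With ``zero_beta=True`` the surrogate mean fields instead
    drop driver ``k`` entirely (its coefficient set to zero).
    """
    if not 0 <= k < model.n_predictors:
        raise ValueError(f"predictor index {k} out of range 0..{model.n_predictors - 1}")
    if model.predictor_panels is None or model.config is None:
        raise ValueError("model was not fitted from panels; use fit_wlm_panels")
    kinds = {"synchrony_preserving": "fourier_synchrony_preserving", "asynchronous": "fourier_independent"}
    if mode not in kinds:
        raise ValueError(f"unknown mode {mode!r}; expected one of {tuple(kinds)}")
    surrogate_spec = SurrogateSpec(kinds[mode], spec.count, spec.seed)

    idx = band_indices(model.timescales, band)
    rh = model_mean_field(model)
    include = rh.include_mask
    observed_msq = rh.msq
    observed_band = float(observed_msq[idx].mean())

    fields = _driver_mean_fields(model)
    betas = model.betas.copy()
    base = np.einsum("ks,kts->ts", np.delete(betas, k, axis=0), np.delete(fields, k, axis=0))
    beta_k = np.zeros_like(betas[k]) if zero_beta else betas[k]

    config = model.config
    sum_msq = np.zeros(len(model.timescales))
    band_means = np.empty(spec.count)
    for i, surr in enumerate(surrogate_stream(model.predictor_panels[k], surrogate_spec)):
        rk = config.power(surr).coefficients.mean(axis=0)
        surface = base + beta_k[None, :] * rk
        msq = _msq(np.abs(surface) ** 2, include)
        sum_msq += msq
        band_means[i] = float(msq[idx].mean())
    pvalue = float((1 + np.sum(band_means >= observed_band)) / (1 + spec.count))
    return InteractionRandomization(
        mode=mode,
        predictor_id=model.predictor_ids[k],
        timescales=model.timescales.copy(),
        observed_msq=observed_msq,
        surrogate_mean_msq=sum_msq / spec.count,
        observed_band_mean=observed_band,
        surrogate_band_means=band_means,
        pvalue=pvalue,
    )
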