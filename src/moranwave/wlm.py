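"""Wavelet linear models: complex regression of transforms on transforms.

A wavelet linear model explains the power-normalized response transforms
``w0`` as a linear combination of predictor transforms with complex,
timescale-dependent coefficients:

.. math::

    w^{(0)}_{n,\\sigma}(t) \\approx \\beta_1(\\sigma) w^{(1)}_{n,\\sigma}(t)
        + \\cdots + \\beta_K(\\sigma) w^{(K)}_{n,\\sigma}(t).

Each ``beta_k(sigma)`` encodes, at one timescale, both the strength
(magnitude) and the phase lag (argument) of the association between
predictor ``k`` and the response — a quarter-cycle delayed influence is a
coefficient with argument pi/2, an inverse (antiphase) influence has
argument pi. The least-squares solution over all stacked (location, time)
cells maximizes the spatial coherence between the response and the fitted
combination at every timescale.

Model assessment uses surrogate-based drop tests (is each predictor's
contribution significant?), leave-one-location-out cross validation (does
the model generalize across space?), exhaustive subset selection, a
coefficient-phase diagnostic, and a spatial permutation test of whether
response-predictor associations are local.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .coherence import band_pvalue, spatial_coherence
from .panel import SpatioTemporalSeries
from .surrogates import SurrogateSpec, surrogate_stream
from .wavelets import NormalizedTransformSet, WaveletConfig, band_indices

__all__ = [
    "WaveletModel",
    "PhaseDiagnostic",
    "ModelCandidate",
    "fit_wlm",
    "fit_wlm_panels",
    "drop_predictor_test",
    "loo_cv_score",
    "select_models",
    "phase_diagnostic",
    "spatial_shuffle_test",
]

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e10
_RIDGE = 1e-10


@dataclass(frozen=True)
class WaveletModel:
    """A fitted wavelet linear model.

    ``betas`` has shape ``(K, S)``; ``fitted`` is the complex ``(N, T, S)``
    surface ``sum_k beta_k(sigma) w_k``; ``model_coherence`` is the
    per-timescale spatial coherence between the response and the fit.
    Panels and the wavelet configuration are retained when the model was
    fitted from time-domain data, enabling surrogate-based tests.
    """

    response_id: str
    predictor_ids: tuple[str, ...]
    betas: np.ndarray
    fitted: np.ndarray
    model_coherence: np.ndarray
    band: tuple[float, float] | None
    response: NormalizedTransformSet
    predictors: tuple[NormalizedTransformSet, ...]
    response_panel: SpatioTemporalSeries | None = None
    predictor_panels: tuple[SpatioTemporalSeries, ...] | None = None
    config: WaveletConfig | None = None

    @property
    def timescales(self) -> np.ndarray:
        return self.response.timescales

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_ids)

    def band_coherence(self, band: tuple[float, float] | None = None) -> float:
        band = band or self.band
        if band is None:
            raise ValueError("no band given and model has none")
        idx = band_indices(self.timescales, band)
        return float(self.model_coherence[idx].mean())


@dataclass(frozen=True)
class PhaseDiagnostic:
    """Comparison of two phase estimators of a predictor's lag.

    ``eta_mean_phase[j]`` is the argument of the mean over cells of
    ``exp(i * eta)`` with ``eta = arg(w0 * conj(wk))`` — the typical
    observed phase difference at each timescale. ``beta_phase`` is the
    fitted coefficient's argument; ``discrepancy`` is their difference
    wrapped to (-pi, pi]. Consistent associations give small discrepancy.
    """

    timescales: np.ndarray
    eta_mean_phase: np.ndarray
    beta_phase: np.ndarray
    discrepancy: np.ndarray


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.mod(phi + np.pi, 2 * np.pi) - np.pi
    return np.where(np.isclose(out, -np.pi), np.pi, out)


def _solve_betas(
    response: NormalizedTransformSet,
    predictors: tuple[NormalizedTransformSet, ...],
    predictor_ids: tuple[str, ...],
    location_subset: np.ndarray | None = None,
    scale_subset: np.ndarray | None = None,
) -> np.ndarray:
    include = response.include_mask
    for p in predictors:
        include = include & p.include_mask
    n_scales = len(response.timescales)
    n_pred = len(predictors)
    scales = range(n_scales) if scale_subset is None else scale_subset
    betas = np.zeros((n_pred, n_scales), dtype=complex)
    loc = slice(None) if location_subset is None else location_subset
    for j in scales:
        m = include[:, j]
        design = np.stack([p.coefficients[loc, :, j][:, m].ravel() for p in predictors], axis=1)
        y = response.coefficients[loc, :, j][:, m].ravel()
        gram = design.conj().T @ design
        jitter = _RIDGE * max(float(np.mean(np.real(np.diag(gram)))), 1.0)
        gram = gram + jitter * np.eye(n_pred)
        if np.linalg.cond(gram) > _COND_LIMIT:
            raise ValueError(
                f"collinear predictors {predictor_ids} at timescale "
                f"{response.timescales[j]:.3f}: condition number exceeds {_COND_LIMIT:g}"
            )
        betas[:, j] = np.linalg.solve(gram, design.conj().T @ y)
    return betas


def fit_wlm(
    response: NormalizedTransformSet,
    predictors: list[NormalizedTransformSet] | tuple[NormalizedTransformSet, ...],
    band: tuple[float, float] | None = None,
    response_id: str = "response",
    predictor_ids: tuple[str, ...] | None = None,
) -> WaveletModel:
    """Fit complex per-timescale coefficients by least squares.

    At each timescale the coefficients minimize the squared residual over
    all stacked included (location, time) cells, via normal equations
    with a tiny ridge jitter on the Gram diagonal for numerical rank
    safety; genuinely collinear predictor sets raise instead of fitting.
    """
    predictors = tuple(predictors)
    if len(predictors) < 1:
        raise ValueError("need at least one predictor")
    for p in predictors + (response,):
        if p.normalization != "power":
            raise ValueError("wavelet linear models require power-normalized transforms")
        if p.coefficients.shape != response.coefficients.shape:
            raise ValueError("response and predictors must share N, T and the timescale grid")
    if predictor_ids is None:
        predictor_ids = tuple(f"x{k + 1}" for k in range(len(predictors)))
    predictor_ids = tuple(predictor_ids)

    betas = _solve_betas(response, predictors, predictor_ids)
    fitted = np.einsum("ks,knts->nts", betas, np.stack([p.coefficients for p in predictors]))
    fitted_set = replace(predictors[0], coefficients=fitted, normalization="power")
    coh = spatial_coherence(response, fitted_set)
    return WaveletModel(
        response_id=response_id,
        predictor_ids=predictor_ids,
        betas=betas,
        fitted=fitted,
        model_coherence=coh.pi,
        band=band,
        response=response,
        predictors=predictors,
    )


def fit_wlm_panels(
    response: SpatioTemporalSeries,
    predictors: list[SpatioTemporalSeries],
    band: tuple[float, float] | None = None,
    config: WaveletConfig | None = None,
    response_id: str = "response",
    predictor_ids: tuple[str, ...] | None = None,
) -> WaveletModel:
    """Transform cleaned panels and fit; retains panels for surrogate tests."""
    config = config or WaveletConfig()
    model = fit_wlm(
        config.power(response),
        [config.power(p) for p in predictors],
        band=band,
        response_id=response_id,
        predictor_ids=predictor_ids,
    )
    return replace(
        model,
        response_panel=response,
        predictor_panels=tuple(predictors),
        config=config,
    )


def drop_predictor_test(
    model: WaveletModel,
    k: int,
    spec: SurrogateSpec,
    band: tuple[float, float] | None = None,
) -> float:
    """Does predictor ``k`` significantly improve the model?

    The statistic is the band-mean coherence between the response and the
    full model fit. The null replaces predictor ``k``'s time-domain panel
    by synchrony-preserving Fourier surrogates — its own spectra and
    synchrony survive, its relationship with the response and the other
    predictors does not — then re-transforms and refits the full model.
    The rank p-value tells whether the observed statistic beats the null.
    """
    if not 0 <= k < model.n_predictors:
        raise ValueError(f"predictor index {k} out of range 0..{model.n_predictors - 1}")
    if model.predictor_panels is None or model.config is None:
        raise ValueError("model was not fitted from panels; use fit_wlm_panels")
    if spec.kind != "fourier_synchrony_preserving":
        raise ValueError("drop tests use synchrony-preserving surrogates")
    band = band or model.band
    if band is None:
        raise ValueError("no timescale band given")
    observed = model.band_coherence(band)
    config = model.config
    fixed = [config.power(p) for p in model.predictor_panels]
    stats = np.empty(spec.count)
    for i, surr in enumerate(surrogate_stream(model.predictor_panels[k], spec)):
        preds = list(fixed)
        preds[k] = config.power(surr)
        refit = fit_wlm(model.response, preds, band=band, predictor_ids=model.predictor_ids)
        stats[i] = refit.band_coherence(band)
    return band_pvalue(observed, stats)


def loo_cv_score(
    response: NormalizedTransformSet,
    predictors: list[NormalizedTransformSet] | tuple[NormalizedTransformSet, ...],
    band: tuple[float, float],
) -> float:
    """Leave-one-location-out goodness of fit within a timescale band.

    For each held-out location the model is fitted on the remaining
    locations and scored on the held-out cells:
    ``1 - sum|w0 - fit|^2 / sum|w0|^2`` over included (t, sigma in band)
    cells; the mean over locations is returned. Out-of-sample scoring
    penalizes predictors that only fit noise.
    """
    predictors = tuple(predictors)
    n = response.coefficients.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 locations")
    idx = band_indices(response.timescales, band)
    include = response.include_mask
    for p in predictors:
        include = include & p.include_mask
    ids = tuple(f"x{k + 1}" for k in range(len(predictors)))
    scores = np.empty(n)
    for held in range(n):
        keep = np.array([i for i in range(n) if i != held])
        betas = _solve_betas(response, predictors, ids, location_subset=keep, scale_subset=idx)
        num = 0.0
        den = 0.0
        for j in idx:
            m = include[:, j]
            y = response.coefficients[held, m, j]
            design = np.stack([p.coefficients[held, m, j] for p in predictors], axis=1)
            resid = y - design @ betas[:, j]
            num += float(np.sum(np.abs(resid) ** 2))
            den += float(np.sum(np.abs(y) ** 2))
        scores[held] = 1.0 - num / den
    return float(scores.mean())


@dataclass(frozen=True)
class ModelCandidate:
    """One retained predictor subset from model selection."""

    predictor_ids: tuple[str, ...]
    model: WaveletModel
    loo_score: float
    drop_pvalues: tuple[float, ...]
    near_top: bool = field(default=False, compare=False)


def select_models(
    response: SpatioTemporalSeries,
    candidate_predictors: dict[str, SpatioTemporalSeries],
    band: tuple[float, float],
    config: WaveletConfig | None = None,
    max_k: int = 5,
    alpha: float = 0.05,
    spec: SurrogateSpec | None = None,
) -> list[ModelCandidate]:
    """Exhaustive subset selection with drop tests and cross validation.

    Every predictor subset of size ``1..max_k`` is fitted; subsets are
    retained only if every predictor's drop test has ``p <= alpha``, then
    ranked by leave-one-out score. Candidates scoring within 90% of the
    top retained score are flagged ``near_top``. Returns the ranked list
    (empty, with a logged diagnostic, if nothing passes).
    """
    if not candidate_predictors:
        raise ValueError("need at least one candidate predictor")
    if max_k > 5:
        raise ValueError("subset enumeration capped at max_k = 5")
    config = config or WaveletConfig()
    spec = spec or SurrogateSpec("fourier_synchrony_preserving", 1000, 0)
    names = list(candidate_predictors)
    w0 = config.power(response)
    transforms = {name: config.power(p) for name, p in candidate_predictors.items()}
    seeds = np.random.SeedSequence(spec.seed).spawn(len(names) * 2 ** len(names))
    seed_iter = iter(seeds)

    retained: list[ModelCandidate] = []
    for size in range(1, min(max_k, len(names)) + 1):
        for subset in itertools.combinations(names, size):
            try:
                model = fit_wlm_panels(
                    response,
                    [candidate_predictors[s] for s in subset],
                    band=band,
                    config=config,
                    predictor_ids=subset,
                )
            except ValueError as err:
                logger.info("skipping subset %s: %s", subset, err)
                continue
            pvals = []
            for k in range(len(subset)):
                sub_spec = SurrogateSpec(
                    spec.kind, spec.count, int(next(seed_iter).generate_state(1)[0] % 2**31)
                )
                pvals.append(drop_predictor_test(model, k, sub_spec, band))
            if any(p > alpha for p in pvals):
                logger.info("subset %s rejected: drop p-values %s", subset, pvals)
                continue
            score = loo_cv_score(w0, [transforms[s] for s in subset], band)
            retained.append(ModelCandidate(subset, model, score, tuple(pvals)))

    if not retained:
        logger.info("model selection retained no subsets (alpha=%.3g, band=%s)", alpha, band)
        return []
    retained.sort(key=lambda c: c.loo_score, reverse=True)
    top = retained[0].loo_score
    return [replace(c, near_top=bool(c.loo_score >= 0.9 * top)) for c in retained]


def phase_diagnostic(model: WaveletModel, k: int) -> PhaseDiagnostic:
    """Compare predictor ``k``'s coefficient phase with the observed one."""
    if not 0 <= k < model.n_predictors:
        raise ValueError(f"predictor index {k} out of range 0..{model.n_predictors - 1}")
    w0 = model.response
    wk = model.predictors[k]
    include = w0.include_mask & wk.include_mask
    n_scales = len(model.timescales)
    theta = np.empty(n_scales)
    for j in range(n_scales):
        cross = w0.coefficients[:, include[:, j], j] * wk.coefficients[:, include[:, j], j].conj()
        eta = np.angle(cross[np.abs(cross) > 0])
        theta[j] = np.angle(np.exp(1j * eta).mean()) if eta.size else 0.0
    beta_phase = np.angle(model.betas[k])
    return PhaseDiagnostic(
        timescales=model.timescales.copy(),
        eta_mean_phase=_wrap_phase(theta),
        beta_phase=_wrap_phase(beta_phase),
        discrepancy=_wrap_phase(theta - beta_phase),
    )


def spatial_shuffle_test(
    response: NormalizedTransformSet,
    predictor: NormalizedTransformSet,
    band: tuple[float, float],
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Are response-predictor associations local?

    The statistic is the band-mean spatial coherence with locations
    matched. The null permutes the predictor's location labels relative
    to the response: if the association were purely regional (the same
    everywhere), permutation would not degrade it and the p-value would
    be uniform; a small p indicates genuinely local associations.
    """
    if n_perm < 100:
        raise ValueError(f"need n_perm >= 100; got {n_perm}")
    n = response.coefficients.shape[0]
    if n < 3:
        raise ValueError("spatial permutation test needs at least 3 locations")
    observed = spatial_coherence(response, predictor).band_mean(band)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        shuffled = replace(predictor, coefficients=predictor.coefficients[perm])
        stats[i] = spatial_coherence(response, shuffled).band_mean(band)
    return band_pvalue(observed, stats)
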