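"""Moran theorem machinery: predicted synchrony, fractions, attribution."""

from dataclasses import replace

import numpy as np
import pytest

from moranwave import (
    SurrogateSpec,
    attribute_synchrony,
    fit_wlm,
    fit_wlm_panels,
    fraction_explained,
    interaction_randomization,
    model_mean_field,
    predicted_synchrony,
    standardize,
    two_driver_scenario,
    wmf,
)

from conftest import LONG_BAND, noise_panel


@pytest.fixture(scope="module")
def joint_model(cfg, scenario_std):
    """Two-driver model of the jointly driven population (phi = 0)."""
    return fit_wlm_panels(
        scenario_std["gamma3"],
        [scenario_std["alpha"], scenario_std["beta_lagged"]],
        band=LONG_BAND,
        config=cfg,
        predictor_ids=("alpha", "beta_lag"),
    )


class TestModelMeanField:
    def test_two_routes_agree(self, joint_model):
        # model_mean_field raises internally if the direct average and the
        # beta-weighted driver mean fields disagree beyond 1e-10
        surface = model_mean_field(joint_model)
        assert np.all(np.isfinite(surface.values))

    def test_unit_beta_single_predictor(self, cfg):
        w1 = cfg.power(standardize(noise_panel(5, 60, seed=1)))
        response = replace(w1, coefficients=w1.coefficients.copy())
        model = fit_wlm(response, [w1])
        np.testing.assert_allclose(
            model_mean_field(model).values, wmf(w1).values, atol=1e-8
        )

    def test_zero_beta_zero_surface(self, cfg):
        w1 = cfg.power(standardize(noise_panel(5, 60, seed=2)))
        model = fit_wlm(w1, [w1])
        zeroed = replace(
            model, betas=np.zeros_like(model.betas), fitted=np.zeros_like(model.fitted)
        )
        assert np.abs(model_mean_field(zeroed).values).max() == 0.0


class TestPredictedSynchrony:
    def test_perfect_model_reproduces_model_magnitude(self, cfg):
        w1 = cfg.power(standardize(noise_panel(5, 60, seed=3)))
        model = fit_wlm(w1, [w1])
        surface = predicted_synchrony(model, w1)
        np.testing.assert_allclose(
            surface.values, np.abs(model_mean_field(model).values), atol=1e-8
        )

    def test_unrelated_response_predicts_nothing(self, cfg):
        vals = []
        for s in range(10):
            w0 = cfg.power(standardize(noise_panel(8, 60, seed=100 + s)))
            w1 = cfg.power(standardize(noise_panel(8, 60, seed=200 + s)))
            model = fit_wlm(w0, [w1], band=LONG_BAND)
            surface = predicted_synchrony(model, w0)
            from moranwave import band_indices

            idx = band_indices(surface.timescales, LONG_BAND)
            vals.append(surface.values[:, idx].mean())
        assert np.mean(vals) < 0.1

    def test_predicted_below_observed(self, cfg):
        """Observed synchrony exceeds model-predicted synchrony: the local
        noise in the driven population is an unmodeled influence."""
        from moranwave import band_indices, mean_squared_synchrony

        wins = 0
        runs = 20
        for s in range(runs):
            sc = two_driver_scenario(0.0, seed=900 + s)
            panels = {k: standardize(v) for k, v in sc.panels.items()}
            model = fit_wlm_panels(
                panels["gamma3"], [panels["alpha"], panels["beta_lagged"]],
                band=LONG_BAND, config=cfg,
            )
            w0 = cfg.power(panels["gamma3"])
            pred = predicted_synchrony(model, w0)
            obs = wmf(w0)
            band = LONG_BAND
            wins += mean_squared_synchrony(pred, band) <= mean_squared_synchrony(obs, band)
        assert wins >= int(0.9 * runs)


class TestFractionExplained:
    def test_moran_identity_exact_for_perfect_model(self, cfg):
        w1 = cfg.power(standardize(noise_panel(6, 60, seed=5)))
        w2 = cfg.power(standardize(noise_panel(6, 60, seed=6)))
        combo = (0.7 - 0.2j) * w1.coefficients + (0.1 + 0.9j) * w2.coefficients
        response = replace(w1, coefficients=combo)
        model = fit_wlm(response, [w1, w2])
        assert fraction_explained(model, response, LONG_BAND) == pytest.approx(1.0, abs=1e-8)

    def test_unrelated_response_fraction_small(self, cfg):
        fracs = []
        for s in range(10):
            w0 = cfg.power(standardize(noise_panel(8, 60, seed=300 + s)))
            w1 = cfg.power(standardize(noise_panel(8, 60, seed=400 + s)))
            model = fit_wlm(w0, [w1], band=LONG_BAND)
            fracs.append(fraction_explained(model, w0, LONG_BAND))
        assert np.mean(fracs) < 0.1

    def test_two_drivers_explain_more_than_one(self, cfg):
        wins = 0
        runs = 15
        band = (10.0, 30.0)
        for s in range(runs):
            sc = two_driver_scenario(0.0, seed=1100 + s)
            panels = {k: standardize(v) for k, v in sc.panels.items()}
            w0 = cfg.power(panels["gamma3"])
            both = fit_wlm_panels(
                panels["gamma3"], [panels["alpha"], panels["beta_lagged"]],
                band=band, config=cfg,
            )
            alone = fit_wlm_panels(panels["gamma3"], [panels["alpha"]], band=band, config=cfg)
            wins += fraction_explained(both, w0, band) > fraction_explained(alone, w0, band)
        assert wins >= int(0.85 * runs)

    def test_rescaling_predictor_does_not_change_fraction(self, cfg):
        sc = two_driver_scenario(0.0, seed=77)
        resp = standardize(sc.gamma1)
        pred = standardize(sc.alpha)
        # positive rescaling of the raw series is absorbed by cleaning and
        # the power normalization, and by beta in the fit
        scaled = pred.with_values(3.7 * pred.values)
        w0 = cfg.power(resp)
        f1 = fraction_explained(fit_wlm(w0, [cfg.power(pred)]), w0, LONG_BAND)
        w_scaled = cfg.power(standardize(scaled))
        f2 = fraction_explained(fit_wlm(w0, [w_scaled]), w0, LONG_BAND)
        assert f1 == pytest.approx(f2, abs=1e-8)


class TestAttributeSynchrony:
    def test_single_predictor_no_interactions(self, cfg):
        sc = two_driver_scenario(0.0, seed=13)
        w0 = cfg.power(standardize(sc.gamma1))
        model = fit_wlm(w0, [cfg.power(standardize(sc.alpha))], predictor_ids=("alpha",))
        part = attribute_synchrony(model, w0, LONG_BAND)
        assert part.fraction_interactions == 0.0
        assert part.fraction_per_predictor["alpha"] == pytest.approx(part.fraction_total)

    def test_conservation(self, joint_model, cfg, scenario_std):
        w0 = cfg.power(scenario_std["gamma3"])
        part = attribute_synchrony(joint_model, w0, LONG_BAND)
        total = sum(part.fraction_per_predictor.values()) + part.fraction_interactions
        assert total == pytest.approx(part.fraction_total, abs=1e-8)
        assert part.fraction_total == pytest.approx(
            fraction_explained(joint_model, w0, LONG_BAND), abs=1e-8
        )

    def test_orthogonal_mean_fields_zero_interaction(self, cfg):
        """Predictors whose mean fields are orthogonal in time contribute
        no cross term."""
        w1 = cfg.power(standardize(noise_panel(4, 60, seed=21)))
        # second predictor: mean field orthogonalized against the first
        c2 = w1.coefficients.copy()[::-1]
        r1 = w1.coefficients.mean(axis=0)
        r2 = c2.mean(axis=0)
        proj = np.zeros_like(r2)
        for j in range(r1.shape[1]):
            a, b = r1[:, j], r2[:, j]
            proj[:, j] = b - (np.vdot(a, b) / np.vdot(a, a)) * a
        c2 = c2 + (proj - r2)[None, :, :]
        w2 = replace(w1, coefficients=c2)
        response = replace(w1, coefficients=w1.coefficients + c2)
        model = fit_wlm(response, [w1, w2], predictor_ids=("a", "b"))
        part = attribute_synchrony(model, response, LONG_BAND)
        assert abs(part.fraction_interactions) < 1e-8

    def test_interaction_sign_flips_with_phase(self, cfg):
        """Reinforcing drivers (phi=0) give positive interaction fractions;
        counteracting drivers (phi=1) give negative ones."""
        band = (10.0, 30.0)
        pos = neg = 0
        runs = 15
        for s in range(runs):
            for phi, counter in ((0.0, "pos"), (1.0, "neg")):
                sc = two_driver_scenario(phi, seed=1300 + s)
                panels = {k: standardize(v) for k, v in sc.panels.items()}
                model = fit_wlm_panels(
                    panels["gamma3"], [panels["alpha"], panels["beta_lagged"]],
                    band=band, config=cfg,
                )
                part = attribute_synchrony(model, cfg.power(panels["gamma3"]), band)
                if counter == "pos":
                    pos += part.fraction_interactions > 0
                else:
                    neg += part.fraction_interactions < 0
        assert pos >= int(0.9 * runs)
        assert neg >= int(0.9 * runs)


class TestInteractionRandomization:
    def test_zero_beta_predictor_changes_nothing(self, cfg):
        sc = two_driver_scenario(0.0, seed=31)
        panels = {k: standardize(v) for k, v in sc.panels.items()}
        model = fit_wlm_panels(
            panels["gamma1"], [panels["alpha"], panels["beta_lagged"]],
            band=LONG_BAND, config=cfg,
        )
        # force the second coefficient to zero: its surrogate draws cannot
        # affect the rebuilt mean field
        betas = model.betas.copy()
        betas[1] = 0
        fitted = np.einsum(
            "ks,knts->nts", betas, np.stack([p.coefficients for p in model.predictors])
        )
        forced = replace(model, betas=betas, fitted=fitted)
        result = interaction_randomization(
            forced, 1, SurrogateSpec("fourier_synchrony_preserving", 20, 0), LONG_BAND
        )
        np.testing.assert_allclose(result.surrogate_mean_msq, result.observed_msq, atol=1e-10)
        np.testing.assert_allclose(
            result.surrogate_band_means, result.observed_band_mean, atol=1e-10
        )

    def test_breaking_alignment_lowers_model_synchrony(self, cfg):
        """At phi=0 the drivers reinforce; destroying their mutual alignment
        (synchrony-preserving surrogates) lowers model band synchrony."""
        wins = 0
        runs = 8
        for s in range(runs):
            sc = two_driver_scenario(0.0, seed=1500 + s)
            panels = {k: standardize(v) for k, v in sc.panels.items()}
            model = fit_wlm_panels(
                panels["gamma3"], [panels["alpha"], panels["beta_lagged"]],
                band=LONG_BAND, config=cfg,
            )
            result = interaction_randomization(
                model, 0, SurrogateSpec("fourier_synchrony_preserving", 100, 40 + s), LONG_BAND
            )
            wins += result.surrogate_band_means.mean() < result.observed_band_mean
        assert wins >= runs - 1

    def test_asynchronous_no_higher_than_synchrony_preserving(self, cfg):
        diffs = []
        for s in range(6):
            sc = two_driver_scenario(0.0, seed=1600 + s)
            panels = {k: standardize(v) for k, v in sc.panels.items()}
            model = fit_wlm_panels(
                panels["gamma3"], [panels["alpha"], panels["beta_lagged"]],
                band=LONG_BAND, config=cfg,
            )
            spec = SurrogateSpec("fourier_synchrony_preserving", 100, 50 + s)
            sync = interaction_randomization(model, 0, spec, LONG_BAND, mode="synchrony_preserving")
            asyn = interaction_randomization(model, 0, spec, LONG_BAND, mode="asynchronous")
            diffs.append(
                asyn.surrogate_band_means.mean() - sync.surrogate_band_means.mean()
            )
        assert np.mean(diffs) <= 0

    def test_shared_phase_surrogates_keep_own_synchrony(self, cfg):
        """Synchrony-preserving surrogates leave the randomized driver's own
        mean squared synchrony essentially unchanged."""
        from moranwave import fourier_surrogates

        sc = two_driver_scenario(0.0, seed=8)
        panel = standardize(sc.alpha)
        original = wmf(cfg.power(panel)).msq
        msqs = [
            wmf(cfg.power(standardize(s))).msq
            for s in fourier_surrogates(
                panel, SurrogateSpec("fourier_synchrony_preserving", 30, 2)
            )
        ]
        ratio = np.mean(msqs, axis=0).sum() / original.sum()
        assert 0.8 < ratio < 1.2
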