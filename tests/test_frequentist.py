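"""Frequentist fits, sampling distributions, interval-censored MLE."""

import numpy as np
import pytest
from scipy import stats

import allergenrisk as ar

from conftest import LOGNORMAL_Z_TRUTH, WEIBULL_TRUTH


class TestFitLognormal:
    def test_two_point_hand_computation(self):
        fit = ar.fit_lognormal([1.0, np.e**2])
        assert fit.location == pytest.approx(1.0)
        assert fit.scale == pytest.approx(np.sqrt(2.0))

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(ar.InvalidParameterError, match="zero"):
            ar.fit_lognormal([np.e] * 4)

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -2.0], [0.0, 1.0]])
    def test_invalid_samples_rejected(self, bad):
        with pytest.raises(ar.InvalidParameterError):
            ar.fit_lognormal(bad)

    def test_standard_errors_match_moment_formulas(self, consumption_sample):
        fit = ar.fit_lognormal(consumption_sample)
        assert fit.se_location == pytest.approx(fit.scale / np.sqrt(fit.n))
        assert fit.se_scale_sq == pytest.approx(
            fit.scale**2 * np.sqrt(2 / (fit.n - 1))
        )


class TestFitExponential:
    def test_rate_prints_as_published_at_mean_77(self):
        sample = np.full(24, 77.0)
        fit = ar.fit_exponential(sample)
        assert round(fit.rate, 3) == 0.013
        assert fit.rate == pytest.approx(1 / 77)

    def test_single_observation(self):
        assert ar.fit_exponential([1.0]).rate == pytest.approx(1.0)

    def test_asymptotic_se_and_override(self):
        sample = np.full(24, 77.0)
        fit = ar.fit_exponential(sample)
        assert fit.se_rate == pytest.approx(fit.rate / np.sqrt(24))
        assert fit.se_rate == pytest.approx(0.00265, abs=2e-5)
        assert ar.fit_exponential(sample, se_rate=0.001).se_rate == 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ar.InvalidParameterError):
            ar.fit_exponential([])


class TestIntervalCensoredMLE:
    def test_weibull_recovery_over_many_seeds(self):
        """Mean recovered shape over 200 synthetic studies within 10% of truth."""
        shapes, scales = [], []
        for s in range(200):
            recs = ar.generate_challenge_data(
                "weibull", WEIBULL_TRUTH, 158, seed=30_000 + s
            )
            fit = ar.fit_interval_censored(recs, "weibull")
            shapes.append(fit.shape)
            scales.append(fit.scale)
        assert np.mean(shapes) == pytest.approx(WEIBULL_TRUTH[0], rel=0.10)
        assert np.mean(scales) == pytest.approx(WEIBULL_TRUTH[1], rel=0.15)

    def test_lognormal_location_se_matches_published_sd(self, lognormal_records):
        """SE of the fitted log-location ~ 0.238 (sigma_Z/sqrt(158))."""
        fit = ar.fit_interval_censored(lognormal_records, "lognormal")
        assert fit.se_location == pytest.approx(0.238, rel=0.25)

    def test_all_reacting_at_first_dose_not_identifiable(self):
        grid = ar.DoseGrid.default()
        recs = [ar.ChallengeRecord(None, grid.doses[0], "left")] * 20
        with pytest.raises(ar.NonIdentifiableError):
            ar.fit_interval_censored(recs, "weibull")

    def test_fine_grid_approaches_uncensored_mle(self):
        """On a near-continuous dose grid the censored MLE matches the
        direct Weibull fit of the latent thresholds within 1%."""
        grid = ar.DoseGrid(tuple(np.geomspace(1e-4, 1e5, 1000)))
        recs = ar.generate_challenge_data(
            "weibull", WEIBULL_TRUTH, 500, grid=grid, seed=31
        )
        latents = np.array([r.latent_mg for r in recs])
        cens = ar.fit_interval_censored(recs, "weibull")
        c, _, scale = stats.weibull_min.fit(latents, floc=0)
        assert cens.shape == pytest.approx(c, rel=0.01)
        assert cens.scale == pytest.approx(scale, rel=0.01)

    def test_matches_lifelines_oracle(self, weibull_records):
        """Independent check against lifelines' interval-censored fitter."""
        lifelines = pytest.importorskip("lifelines")
        fit = ar.fit_interval_censored(weibull_records, "weibull")
        lo = np.array(
            [r.lower_mg if r.lower_mg is not None else 1e-9
             for r in weibull_records]
        )
        hi = np.array(
            [r.upper_mg if r.upper_mg is not None else np.inf
             for r in weibull_records]
        )
        wf = lifelines.WeibullFitter()
        wf.fit_interval_censoring(lo, hi)
        # lifelines: rho_ = shape, lambda_ = scale
        assert fit.shape == pytest.approx(wf.rho_, rel=0.01)
        assert fit.scale == pytest.approx(wf.lambda_, rel=0.01)


class TestParameterDraws:
    def test_location_draw_sd_matches_closed_form(self):
        fit = ar.LognormalParams(-3.719, 0.747, 350, 0.747 / np.sqrt(350),
                                 0.747**2 * np.sqrt(2 / 349))
        draws = ar.draw_lognormal_params(fit, 10**5, seed=41)
        assert draws[:, 0].std(ddof=1) == pytest.approx(
            0.747 / np.sqrt(350), rel=0.02
        )
        # published sampling SD of mu_X rounds to 0.039
        assert round(draws[:, 0].std(ddof=1), 3) == 0.040 or round(
            draws[:, 0].std(ddof=1), 3
        ) == 0.039

    def test_variance_draws_have_chi_square_mean_and_positivity(self):
        fit = ar.LognormalParams(-3.719, 0.747, 350, 0.747 / np.sqrt(350),
                                 0.747**2 * np.sqrt(2 / 349))
        draws = ar.draw_lognormal_params(fit, 10**5, seed=42)
        assert np.all(draws[:, 1] > 0)
        assert np.mean(draws[:, 1] ** 2) == pytest.approx(0.747**2, rel=0.01)

    def test_location_draws_symmetric_about_estimate(self):
        fit = ar.LognormalParams(1.0, 0.5, 50, 0.5 / np.sqrt(50),
                                 0.25 * np.sqrt(2 / 49))
        draws = ar.draw_lognormal_params(fit, 10**5, seed=43)
        assert abs(stats.skew(draws[:, 0])) < 0.03

    def test_large_n_collapses_to_point_estimate(self):
        fit = ar.LognormalParams(-3.719, 0.747, 10**8, 1e-9, 1e-9)
        draws = ar.draw_lognormal_params(fit, 1000, seed=44)
        assert np.allclose(draws[:, 0], -3.719, atol=1e-3)
        assert np.allclose(draws[:, 1], 0.747, atol=1e-3)

    def test_normal_draw_percentiles_match_published_band(self):
        """a_Z ~ N(0.382, 0.027): 2.5/97.5 percentiles ~ 0.329/0.435."""
        draws = ar.draw_normal_params(0.382, 0.027, 10**5, seed=45, positive=True)
        assert np.quantile(draws, 0.025) == pytest.approx(0.329, rel=0.02)
        assert np.quantile(draws, 0.975) == pytest.approx(0.435, rel=0.02)

    def test_tiny_se_concentrates_at_estimate(self):
        draws = ar.draw_normal_params(0.382, 1e-12, 100, seed=46)
        assert np.allclose(draws, 0.382)

    def test_excessive_rejection_rate_is_an_error(self):
        with pytest.raises(ar.InvalidParameterError, match="rejection"):
            ar.draw_normal_params(0.001, 1.0, 100, seed=47, positive=True)

    def test_fit_and_draw_round_trip_covers_truth(self):
        """3-SE interval around the refitted location covers truth in
        >= 99% of seeded repetitions."""
        hits = 0
        reps = 150
        for s in range(reps):
            x = ar.generate_consumption((-3.719, 0.747), 350, seed=50_000 + s)
            fit = ar.fit_lognormal(x)
            hits += abs(fit.location + 3.719) < 3 * fit.se_location
        assert hits / reps >= 0.99
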