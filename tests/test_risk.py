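"""Risk engine: closed form, the two MC estimators, case runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import allergenrisk as ar
from allergenrisk.risk import _closed_form_risk_vec


class TestClosedForm:
    def test_symmetric_configuration_gives_one_half(self):
        assert ar.closed_form_risk((0, 1), (0, 1), (0, 1)) == pytest.approx(0.5)

    def test_threshold_location_limits(self):
        assert ar.closed_form_risk((0, 1), (0, 1), (100, 1)) < 1e-12
        assert ar.closed_form_risk((0, 1), (0, 1), (-100, 1)) > 1 - 1e-12

    def test_all_zero_scales_rejected(self):
        with pytest.raises(ar.InvalidParameterError):
            ar.closed_form_risk((0, 0), (0, 0), (0, 0))

    def test_published_plug_in_configuration(self):
        r = ar.closed_form_risk(**{k: v for k, v in zip(
            ("x", "y", "z"), ar.PEANUT_CASE_A.values())})
        assert 100 * r == pytest.approx(9.84, abs=0.01)

    def test_accepts_lognormal_params_objects(self, consumption_sample):
        fit = ar.fit_lognormal(consumption_sample)
        direct = ar.closed_form_risk(
            (fit.location, fit.scale), (3.5, 1.3), (4.1, 3.0)
        )
        assert ar.closed_form_risk(fit, (3.5, 1.3), (4.1, 3.0)) == direct

    @given(shift=st.floats(min_value=-3.0, max_value=3.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_consumption_location(self, shift):
        base = ar.closed_form_risk((-3.7, 0.7), (3.5, 1.3), (4.1, 3.0))
        shifted = ar.closed_form_risk((-3.7 + shift, 0.7), (3.5, 1.3), (4.1, 3.0))
        if shift >= 0:
            assert shifted >= base
        else:
            assert shifted <= base


def _ln_sampler(mu, sigma):
    return lambda n, rng: rng.lognormal(mu, sigma, n)


class TestIndicatorEstimator:
    def test_agrees_with_closed_form_within_binomial_error(self):
        p_exact = ar.closed_form_risk(**ar.PEANUT_CASE_A)
        n = 10**6
        p_mc = ar.simulate_risk_indicator(
            _ln_sampler(*ar.PEANUT_CASE_A["x"]),
            _ln_sampler(*ar.PEANUT_CASE_A["y"]),
            _ln_sampler(*ar.PEANUT_CASE_A["z"]),
            n=n, seed=10,
        )
        assert abs(p_mc - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / n)

    def test_zero_threshold_means_certain_reaction(self):
        p = ar.simulate_risk_indicator(
            _ln_sampler(0, 1), _ln_sampler(0, 1),
            lambda n, rng: np.zeros(n), n=1000, seed=1,
        )
        assert p == 1.0

    def test_infinite_threshold_means_no_reaction(self):
        p = ar.simulate_risk_indicator(
            _ln_sampler(0, 1), _ln_sampler(0, 1),
            lambda n, rng: np.full(n, np.inf), n=1000, seed=1,
        )
        assert p == 0.0

    def test_zero_iterations_rejected(self):
        with pytest.raises(ar.InvalidParameterError):
            ar.simulate_risk_indicator(
                _ln_sampler(0, 1), _ln_sampler(0, 1), _ln_sampler(0, 1),
                n=0, seed=1,
            )


class TestDoseResponseEstimator:
    def test_fixed_exposure_evaluates_weibull_cdf(self):
        w = ar.WeibullParams(0.38, 229.6, 1.0, 1.0)
        p = ar.simulate_risk_doseresponse(
            lambda n, rng: np.full(n, 1.87),
            lambda n, rng: np.ones(n),
            w.cdf, n=100, seed=2,
        )
        assert p == pytest.approx(1 - np.exp(-((1.87 / 229.6) ** 0.38)), rel=1e-12)
        assert p == pytest.approx(0.149, abs=0.002)

    def test_saturated_dose_response_gives_certainty(self):
        p = ar.simulate_risk_doseresponse(
            _ln_sampler(0, 1), _ln_sampler(0, 1),
            lambda x: np.ones_like(x), n=500, seed=3,
        )
        assert p == 1.0

    def test_equivalence_with_indicator_in_expectation(self):
        """Counting exceedances of sampled thresholds and averaging the
        threshold CDF at the exposures estimate the same risk."""
        n = 10**6
        w = ar.WeibullParams(0.38, 229.6, 1.0, 1.0)
        x, y = (-3.719, 0.747), (3.496, 1.283)
        rng = np.random.default_rng(4)
        p_ind = ar.simulate_risk_indicator(
            _ln_sampler(*x), _ln_sampler(*y),
            lambda m, r: 229.6 * r.weibull(0.38, m), n=n, rng=rng,
        )
        rng2 = np.random.default_rng(5)
        xs = rng2.lognormal(*x, n)
        ys = rng2.lognormal(*y, n)
        f = w.cdf(xs * ys)
        p_dr = float(f.mean())
        se = np.sqrt(p_ind * (1 - p_ind) / n + f.var() / n)
        assert abs(p_ind - p_dr) < 3 * se


class TestRunCase:
    def test_degenerate_outer_loop_equals_single_indicator_run(self):
        """K=1 plug-in run reproduces one indicator simulation on the
        same derived substream."""
        spec = ar.case_a(K=1, n=5000, seed=9)
        dist = ar.run_case(spec)
        rep_seed = np.random.SeedSequence(9).spawn(4)[3].spawn(1)[0]
        rng = np.random.default_rng(rep_seed)
        expected = ar.simulate_risk_indicator(
            _ln_sampler(*ar.PEANUT_CASE_A["x"]),
            _ln_sampler(*ar.PEANUT_CASE_A["y"]),
            _ln_sampler(*ar.PEANUT_CASE_A["z"]),
            n=5000, rng=rng,
        )
        assert dist.risks[0] == expected
        assert dist.sd_is_simulation_error_only

    def test_identical_spec_and_seed_reproduce_distribution(self):
        a = ar.run_case(ar.case_b(K=50, n=2000, seed=12))
        b = ar.run_case(ar.case_b(K=50, n=2000, seed=12))
        assert np.array_equal(a.risks, b.risks)

    def test_summary_percentiles_are_order_consistent(self):
        d = ar.run_case(ar.case_b(K=200, n=1000, seed=13))
        assert d.p2_5 <= d.median <= d.p97_5
        assert d.sd >= 0
        shuffled = ar.RiskDistribution(
            np.random.default_rng(0).permutation(d.risks)
        )
        for key, val in d.summary().items():
            assert shuffled.summary()[key] == pytest.approx(val, rel=1e-12)

    def test_calculated_mode_matches_scalar_closed_form(self):
        spec = ar.case_b(mode="calculated", K=100, seed=14)
        dist = ar.run_case(spec)
        root = np.random.SeedSequence(14)
        ss = root.spawn(4)
        px = spec.consumption.draw_params(100, np.random.default_rng(ss[0]), True)
        py = spec.concentration.draw_params(100, np.random.default_rng(ss[1]), True)
        pz = spec.threshold.draw_params(100, np.random.default_rng(ss[2]), True)
        manual = [
            ar.closed_form_risk(px[k], py[k], pz[k]) for k in range(100)
        ]
        assert np.allclose(dist.risks, manual)

    def test_risk_monotone_under_stochastically_larger_inputs(self):
        base = ar.run_case(ar.case_b(mode="calculated", K=400, seed=15)).mean
        richer = ar.PEANUT_CASE_B.copy()
        richer["y"] = (richer["y"][0] + 1.0, *richer["y"][1:])
        up = ar.run_case(
            ar.case_b(params=richer, mode="calculated", K=400, seed=15)
        ).mean
        tougher = ar.PEANUT_CASE_B.copy()
        tougher["z"] = (tougher["z"][0] + 1.0, *tougher["z"][1:])
        down = ar.run_case(
            ar.case_b(params=tougher, mode="calculated", K=400, seed=15)
        ).mean
        assert up > base > down

    def test_closed_form_mode_requires_lognormal_inputs(self):
        with pytest.raises(ar.InvalidParameterError):
            ar.CaseSpec(
                case_id="C",
                consumption=ar.LognormalInput(-3.7, 0.7),
                concentration=ar.ExponentialInput(0.013),
                threshold=ar.WeibullInput(0.38, 229.6),
                risk_method="closed_form",
            )

    def test_case_d_runs_from_posteriors(self, consumption_sample,
                                          concentration_sample,
                                          weibull_records):
        post = ar.weibull_threshold_mcmc(
            weibull_records, K=500, seed=16,
            mcmc_config=ar.MCMCConfig(n_iter=3000, n_burnin=1000),
        )
        gamma = ar.exponential_gamma_posterior(1e-3, 1e-3, concentration_sample)
        spec = ar.case_d(consumption_sample, gamma, post, K=100, n=2000, seed=17)
        d = ar.run_case(spec)
        assert 0.0 < d.mean < 1.0
        assert "bootstrap" in spec.metadata["consumption_note"]


def test_vectorized_closed_form_matches_scalar():
    rng = np.random.default_rng(18)
    xp = np.column_stack([rng.normal(-3.7, 0.1, 20), rng.uniform(0.5, 1, 20)])
    yp = np.column_stack([rng.normal(3.5, 0.3, 20), rng.uniform(1, 1.5, 20)])
    zp = np.column_stack([rng.normal(4.1, 0.3, 20), rng.uniform(2.5, 3.5, 20)])
    vec = _closed_form_risk_vec(xp, yp, zp)
    for k in range(20):
        assert vec[k] == pytest.approx(
            ar.closed_form_risk(xp[k], yp[k], zp[k])
        )
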