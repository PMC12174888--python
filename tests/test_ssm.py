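"""Kalman filtering, MLE/MAP fitting, empirical priors and risk readout."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import lapsecast as lc
from conftest import random_params
from lapsecast.ssm import (
    LAPSE_CHANNEL,
    VAR_FLOOR,
    fit_map_obs,
    fit_mle_obs,
    series_to_obs,
)
from oracle_utils import joint_gaussian_loglik


class TestKalmanFilter:
    def test_single_step_closed_form(self):
        # k=1, T=1, A=1, c=0, R=1, stationary var 1/(1-b^2) -> with b=0 the
        # predictive variance is 1+1=2 and loglik = -0.5*ln(2*pi*2) at y=0
        params = lc.SsmParams(A=[[1.0]], c=[0.0], r=[1.0], b=[0.0])
        fr = lc.kalman_filter(params, (np.zeros((1, 1)), np.ones((1, 1), bool)))
        assert fr.loglik == pytest.approx(-0.5 * math.log(2 * math.pi * 2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_unrolled_joint_gaussian(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 3)
        n = rng.integers(1, 5)
        T = rng.integers(1, 6)
        params = random_params(rng, k=k, n=n)
        y = rng.normal(0.5, 0.5, size=(T, n))
        mask = rng.random((T, n)) < 0.8
        fr = lc.kalman_filter(params, (y, mask))
        want = joint_gaussian_loglik(params, y, mask)
        assert fr.loglik == pytest.approx(want, abs=1e-8)

    def test_fully_masked_days_propagate_prior(self):
        rng = np.random.default_rng(0)
        params = random_params(rng)
        T = 4
        y = np.zeros((T, 10))
        mask = np.zeros((T, 10), dtype=bool)
        fr = lc.kalman_filter(params, (y, mask))
        assert fr.loglik == 0.0
        np.testing.assert_allclose(fr.filt_mean, 0.0)
        # prior propagation: P stays at the stationary covariance
        np.testing.assert_allclose(
            np.diagonal(fr.filt_cov, axis1=1, axis2=2),
            np.tile(params.stationary_var(), (T, 1)),
            rtol=1e-10,
        )

    def test_masking_equals_channel_deletion(self):
        rng = np.random.default_rng(3)
        params = random_params(rng, n=6)
        T = 8
        y = rng.normal(0.5, 0.4, size=(T, 6))
        mask = np.ones((T, 6), dtype=bool)
        mask[:, 2] = False  # mask channel 2 everywhere
        fr_masked = lc.kalman_filter(params, (y, mask))
        keep = [0, 1, 3, 4, 5]
        smaller = lc.SsmParams(
            A=params.A[keep], c=params.c[keep], r=params.r[keep], b=params.b
        )
        fr_small = lc.kalman_filter(
            params=smaller, obs=(y[:, keep], np.ones((T, 5), dtype=bool))
        )
        assert fr_masked.loglik == pytest.approx(fr_small.loglik, rel=1e-12)
        np.testing.assert_allclose(fr_masked.filt_mean, fr_small.filt_mean)

    def test_sequence_of_observations_api(self):
        params = lc.SsmParams(A=[[1.0]], c=[0.0], r=[1.0], b=[0.5])
        obs = [lc.SsmObservation(y=np.array([0.3]), mask=np.array([True]))] * 3
        fr = lc.kalman_filter(params, obs)
        assert np.isfinite(fr.loglik)


class TestMleFit:
    def test_ascent_over_init(self, small_cohort):
        cohort, _ = small_cohort
        p = cohort.participants[0]
        y, mask = series_to_obs(p, (1, 30), (1, 29), cohort.ordinal_scale)
        rng = np.random.default_rng(1)
        init = random_params(rng)
        ll_init = lc.kalman_filter(init, (y, mask)).loglik
        res = fit_mle_obs(y, mask, init=init, seed=0, n_restarts=1)
        assert res.loglik >= ll_init

    def test_constant_channel_hits_variance_floor(self):
        T = 40
        y = np.full((T, 10), 0.5)
        mask = np.ones((T, 10), dtype=bool)
        res = fit_mle_obs(y, mask, seed=0, n_restarts=1, maxiter=400)
        # constant data: at least the bulk of channels drive their noise
        # variance to (near) the lower bound
        assert np.median(res.params.r) < 10 * VAR_FLOOR

    def test_parameter_recovery_moderate_series(self):
        rng = np.random.default_rng(42)
        true = random_params(rng, k=2, n=10)
        _, y = true.simulate(600, rng)
        res = fit_mle_obs(y, np.ones_like(y, dtype=bool), seed=0, maxiter=600)
        got = res.params
        assert np.abs(got.b - true.b).max() < 0.12
        assert np.abs(got.A - true.A).max() < 0.12

    def test_canonical_form(self, small_cohort):
        cohort, _ = small_cohort
        res = lc.mle_fit(cohort.participants[1], ordinal_scale=cohort.ordinal_scale)
        p = res.params
        assert (np.diff(p.b) <= 1e-12).all()  # descending transition diagonal
        assert (p.A.sum(axis=0) >= -1e-9).all()  # non-negative column sums


class TestMapFit:
    def test_flat_prior_limit_matches_mle(self, small_cohort):
        cohort, _ = small_cohort
        p = cohort.participants[2]
        y, mask = series_to_obs(p, (1, 40), (1, 40), cohort.ordinal_scale)
        mle = fit_mle_obs(y, mask, seed=0, maxiter=500)
        flat = lc.PriorSpec.around(mle.params, 1e6)
        mp = fit_map_obs(y, mask, flat, init=mle.params, seed=0, maxiter=500)
        assert mp.loglik == pytest.approx(mle.loglik, abs=0.1)
        np.testing.assert_allclose(mp.params.b, mle.params.b, atol=0.05)

    def test_tight_prior_limit_returns_prior_centre(self, small_cohort):
        cohort, _ = small_cohort
        p = cohort.participants[3]
        y, mask = series_to_obs(p, (1, 30), (1, 29), cohort.ordinal_scale)
        rng = np.random.default_rng(5)
        centre = random_params(rng)
        tight = lc.PriorSpec.around(centre, 1e-6)
        res = fit_map_obs(y, mask, tight, seed=0, maxiter=500)
        got = res.params.canonicalize()
        want = centre.canonicalize()
        assert np.abs(got.A - want.A).max() < 1e-3
        assert np.abs(got.b - want.b).max() < 1e-3
        assert np.abs(np.log(got.r) - np.log(want.r)).max() < 1e-3

    def test_map_to_mle_convergence_is_monotone_in_prior_scale(self, small_cohort):
        cohort, _ = small_cohort
        p = cohort.participants[4]
        y, mask = series_to_obs(p, (1, 35), (1, 34), cohort.ordinal_scale)
        mle = fit_mle_obs(y, mask, seed=0, maxiter=500)
        rng = np.random.default_rng(6)
        centre = random_params(rng)
        gaps = []
        for scale in (0.05, 0.5, 5.0, 500.0):
            pri = lc.PriorSpec.around(centre, scale)
            res = fit_map_obs(y, mask, pri, init=mle.params, seed=0, maxiter=500)
            gaps.append(mle.loglik - res.loglik)
        assert all(g >= -0.05 for g in gaps)  # MLE is the likelihood optimum
        assert gaps[-1] < gaps[0]  # wide priors close the gap
        assert gaps[-1] < 0.5

    def test_positive_risk_with_zero_observed_lapses(self, small_cohort):
        """MAP's purpose: lapse risk stays positive for never-lapsed windows."""
        cohort, truth = small_cohort
        priors = lc.build_priors(
            lc.Cohort(cohort.participants[5:15], cohort.ordinal_scale), seed=0
        )
        # construct a 15-day window with no lapses from a zero-lapse participant
        p = next(q for q in cohort if q.lapse[:15].sum() == 0)
        y, mask = series_to_obs(p, (1, 15), (1, 14), cohort.ordinal_scale)
        res = fit_map_obs(y, mask, priors, seed=0)
        fr = lc.kalman_filter(res.params, (y, mask))
        score = lc.predict_risk(res.params, fr.filt_mean[-1], fr.filt_cov[-1], 0)
        assert 0.0 < score < 1.0
        assert score > 1e-8


class TestBuildPriors:
    def test_moment_matching_oracle(self, small_cohort):
        """Gaussian components: fitted mean/scale equal sample moments."""
        cohort, _ = small_cohort
        training = lc.Cohort(cohort.participants[:6], cohort.ordinal_scale)
        cache = {}
        priors = lc.build_priors(training, sd_floor=0.01, seed=0, mle_cache=cache)
        A = np.stack([cache[p.participant_id].A for p in training])
        np.testing.assert_allclose(priors.a_mean, A.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            priors.a_sd, np.maximum(A.std(axis=0, ddof=1), 0.01), atol=1e-12
        )
        from lapsecast.ssm import interior_log_moments

        logr = np.log(np.stack([cache[p.participant_id].r for p in training]))
        want_mean, _ = interior_log_moments(logr, 0.01)
        np.testing.assert_allclose(priors.logr_mean, want_mean, atol=1e-12)

    def test_identical_training_data_floors_scales(self, small_cohort):
        cohort, _ = small_cohort
        base = cohort.participants[0]
        clones = [
            lc.ParticipantSeries(f"c{i}", base.study_length, base.start_weekday,
                                 base.ema, base.lapse.copy())
            for i in range(3)
        ]
        priors = lc.build_priors(
            lc.Cohort(clones, cohort.ordinal_scale), sd_floor=0.05, seed=0
        )
        np.testing.assert_allclose(priors.a_sd, 0.05)
        np.testing.assert_allclose(priors.b_sd, 0.05)
        mle = lc.mle_fit(base, ordinal_scale=cohort.ordinal_scale, seed=0)
        np.testing.assert_allclose(priors.a_mean, mle.params.A, atol=1e-9)

    def test_heterogeneity_widens_priors(self):
        scales = []
        for eta in (0.5, 2.5):
            co, _ = lc.generate_cohort(
                lc.GeneratorConfig(n_participants=10, study_length=60,
                                   heterogeneity=eta), seed=17,
            )
            pri = lc.build_priors(co, sd_floor=0.0 + 1e-9, seed=0)
            scales.append(float(np.mean(pri.a_sd)))
        assert scales[1] > scales[0]

    def test_too_few_participants_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            lc.build_priors(lc.Cohort(cohort.participants[:1], cohort.ordinal_scale))


class TestPredictRisk:
    def _state(self, rng, params):
        m = rng.normal(0, 0.5, size=params.k)
        P = np.diag(rng.uniform(0.2, 1.0, size=params.k))
        return m, P

    def test_same_day_analytic_equals_monte_carlo(self):
        rng = np.random.default_rng(2)
        params = random_params(rng)
        m, P = self._state(rng, params)
        a = lc.predict_risk(params, m, P, 0, method="analytic")
        n = 40000
        mc = lc.predict_risk(params, m, P, 0, method="monte_carlo",
                             n_rollouts=n, seed=1)
        se = math.sqrt(a * (1 - a) / n)
        assert abs(a - mc) < 3 * se + 1e-9

    def test_independent_days_product_form(self):
        # B = 0 removes cross-day dependence: two days at p=0.5 -> 0.75
        params = lc.SsmParams(
            A=np.vstack([np.zeros((9, 1)), [[1.0]]]),
            c=np.concatenate([np.zeros(9), [0.5]]),
            r=np.full(10, 1.0),
            b=[0.0],
        )
        m, P = np.zeros(1), np.eye(1) * 1.0
        # per-day p = Phi((0.5-0.5)/sd) = 0.5 each day
        a1 = lc.predict_risk(params, m, P, 1, method="analytic")
        assert a1 == pytest.approx(0.75, abs=1e-9)

    def test_monte_carlo_matches_analytic_when_b_zero(self):
        rng = np.random.default_rng(4)
        params = random_params(rng)
        params = lc.SsmParams(A=params.A, c=params.c, r=params.r,
                              b=np.zeros(params.k))
        m, P = self._state(rng, params)
        a = lc.predict_risk(params, m, P, 3, method="analytic")
        n = 20000
        mc = lc.predict_risk(params, m, P, 3, method="monte_carlo",
                             n_rollouts=n, seed=5)
        se = math.sqrt(max(a * (1 - a), 1e-6) / n)
        assert abs(a - mc) < 3 * se + 2e-3

    def test_scores_open_unit_interval_and_monotone_in_horizon(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            params = random_params(rng)
            m, P = self._state(rng, params)
            scores = [
                lc.predict_risk(params, m, P, k, method="analytic")
                for k in (0, 3, 7)
            ]
            assert all(0.0 < s < 1.0 for s in scores)
            assert scores[0] <= scores[1] <= scores[2]

    def test_negative_horizon_rejected(self):
        rng = np.random.default_rng(7)
        params = random_params(rng)
        with pytest.raises(ValueError):
            lc.predict_risk(params, np.zeros(2), np.eye(2), -1)
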