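"""Heterogeneous HMM: emission marginalization, forward-backward vs
path-enumeration oracle, EM behavior, model selection, forecasting."""

import numpy as np
import pytest

from _oracles import brute_force_posterior as _brute_force
from _oracles import random_params as _random_params
from _oracles import random_sequence as _random_sequence
from moodcast.hmm import (
    HHMMParams,
    emission_loglik,
    fit_em,
    forward_backward,
    hmm_forecast,
    select_K,
    sequence_loglik,
)


class TestEmission:
    def test_fully_missing_day_gives_zero_loglik(self, tiny_hmm_params):
        ll = emission_loglik(tiny_hmm_params, np.array([np.nan, np.nan, np.nan]))
        np.testing.assert_array_equal(ll, np.zeros(2))

    def test_single_gaussian_closed_form(self):
        params = HHMMParams(
            start_probs=[1.0], transition=[[1.0]], gauss_means=[[0.0]], gauss_sds=[[1.0]], bern_p=None
        )
        x = 0.73
        ll = emission_loglik(params, np.array([x]))
        assert ll[0] == pytest.approx(-0.5 * np.log(2 * np.pi) - x**2 / 2, abs=1e-12)

    def test_observed_features_sum(self, tiny_hmm_params):
        both = emission_loglik(tiny_hmm_params, np.array([0.5, -0.2, np.nan]))
        first = emission_loglik(tiny_hmm_params, np.array([0.5, np.nan, np.nan]))
        second = emission_loglik(tiny_hmm_params, np.array([np.nan, -0.2, np.nan]))
        np.testing.assert_allclose(both, first + second, atol=1e-12)

    def test_nonfinite_value_rejected(self, tiny_hmm_params):
        with pytest.raises(ValueError):
            emission_loglik(tiny_hmm_params, np.array([np.inf, 0.0, 1.0]))


class TestForwardBackward:
    def test_t1_posterior_proportional_to_start_times_emission(self, tiny_hmm_params):
        seq = np.array([[0.3, 0.1, 1.0]])
        post = forward_backward(tiny_hmm_params, seq)
        ll = emission_loglik(tiny_hmm_params, seq[0])
        expected = tiny_hmm_params.start_probs * np.exp(ll)
        expected /= expected.sum()
        np.testing.assert_allclose(post.gamma[0], expected, atol=1e-12)

    def test_matches_enumeration_oracle_many_instances(self):
        """Forward-backward equals brute-force path enumeration on random
        small instances with mixed missingness (100 seeds)."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            K = int(rng.integers(1, 4))
            T = int(rng.integers(1, 7))
            Fc = int(rng.integers(1, 4))
            with_bern = bool(rng.integers(0, 2))
            params = _random_params(rng, K, Fc, with_bern)
            seq = _random_sequence(rng, T, Fc, with_bern, missing=float(rng.uniform(0, 0.6)))
            post = forward_backward(params, seq)
            gamma_bf, ll_bf = _brute_force(params, seq)
            np.testing.assert_allclose(post.gamma, gamma_bf, atol=1e-8)
            assert post.log_likelihood == pytest.approx(ll_bf, abs=1e-8)
            np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_fully_missing_day_follows_chain(self):
        """A day with no observations takes its posterior purely from the
        chain propagated through its neighbors."""
        params = HHMMParams(
            start_probs=[0.5, 0.5],
            transition=[[0.7, 0.3], [0.4, 0.6]],
            gauss_means=[[-1.0], [1.0]],
            gauss_sds=[[0.5], [0.5]],
            bern_p=None,
        )
        seq = np.array([[-1.0], [np.nan], [1.0]])
        post = forward_backward(params, seq)
        gamma_bf, _ = _brute_force(params, seq)
        np.testing.assert_allclose(post.gamma, gamma_bf, atol=1e-10)
        # hand propagation for the middle day: alpha1 ~ (gamma0 A), beta via A b2
        A = params.transition
        b0 = np.exp(emission_loglik(params, seq[0]))
        b2 = np.exp(emission_loglik(params, seq[2]))
        alpha0 = np.array(params.start_probs) * b0
        alpha1 = alpha0 @ A  # no emission term on the missing day
        beta1 = A @ b2
        expected = alpha1 * beta1
        expected /= expected.sum()
        np.testing.assert_allclose(post.gamma[1], expected, atol=1e-10)


class TestMarginalization:
    def test_fully_missing_feature_equals_reduced_model(self):
        """Dropping a feature's observations entirely gives the same sequence
        likelihood as a model without that feature (50 random instances)."""
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            K = int(rng.integers(1, 4))
            Fc = int(rng.integers(2, 5))
            params = _random_params(rng, K, Fc, with_bern=True)
            T = int(rng.integers(2, 7))
            seq = _random_sequence(rng, T, Fc, True, missing=0.2)
            f = int(rng.integers(Fc))
            seq[:, f] = np.nan
            ll_full = sequence_loglik(params, seq)
            reduced = params.drop_continuous_feature(f)
            seq_reduced = np.delete(seq, f, axis=1)
            ll_reduced = sequence_loglik(reduced, seq_reduced)
            assert ll_full == pytest.approx(ll_reduced, abs=1e-8)


class TestEM:
    def test_single_state_degeneracy(self):
        rng = np.random.default_rng(3)
        X = rng.normal([2.0, -1.0], [1.5, 0.6], size=(400, 2))
        b = (rng.random(400) < 0.3).astype(float)
        seq = np.column_stack([X, b])
        seq[rng.random(seq.shape) < 0.25] = np.nan
        params, trace = fit_em([seq], K=1, seed=0, n_restarts=1)
        obs = ~np.isnan(seq)
        for f in range(2):
            vals = seq[obs[:, f], f]
            assert params.gauss_means[0, f] == pytest.approx(vals.mean(), abs=1e-6)
            assert params.gauss_sds[0, f] == pytest.approx(vals.std(ddof=0), abs=1e-6)
        sport = seq[obs[:, 2], 2]
        assert params.bern_p[0] == pytest.approx(sport.mean(), abs=1e-6)

    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(4)
        seqs = [_random_sequence(rng, 60, 3, True, 0.3) for _ in range(5)]
        _, trace = fit_em(seqs, K=2, seed=1, n_restarts=2, max_iter=30)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        seqs = [_random_sequence(rng, 40, 2, True, 0.2) for _ in range(4)]
        p1, t1 = fit_em(seqs, K=2, seed=9, n_restarts=2, max_iter=15)
        p2, t2 = fit_em(seqs, K=2, seed=9, n_restarts=2, max_iter=15)
        np.testing.assert_array_equal(p1.gauss_means, p2.gauss_means)
        np.testing.assert_array_equal(p1.transition, p2.transition)
        np.testing.assert_array_equal(t1, t2)


class TestSelectK:
    def test_free_parameter_arithmetic(self):
        params = HHMMParams(
            start_probs=np.full(2, 0.5),
            transition=np.full((2, 2), 0.5),
            gauss_means=np.zeros((2, 6)),
            gauss_sds=np.ones((2, 6)),
            bern_p=np.full(2, 0.5),
        )
        # (K-1) + K(K-1) + 2*6K + K = 1 + 2 + 24 + 2
        assert params.n_free_params() == 29

    def test_aic_formula(self):
        # AIC = 2p - 2l with l = -1000, K = 2 -> 2*29 + 2000
        assert 2 * 29 - 2 * (-1000) == 2058

    def test_single_candidate_is_argmin(self):
        rng = np.random.default_rng(6)
        seqs = [_random_sequence(rng, 30, 2, True, 0.2) for _ in range(3)]
        df = select_K(seqs, [2], seed=0, n_restarts=1, max_iter=10)
        assert df.attrs["best_BIC"] == 2 and df.attrs["best_AIC"] == 2


class TestForecast:
    def test_h0_identity_and_identity_transition(self, tiny_hmm_params):
        g = np.array([0.3, 0.7])
        np.testing.assert_array_equal(hmm_forecast(tiny_hmm_params, g, 0), g)
        eye = HHMMParams(
            start_probs=[0.5, 0.5], transition=np.eye(2), gauss_means=[[0.0], [1.0]],
            gauss_sds=[[1.0], [1.0]],
        )
        np.testing.assert_allclose(hmm_forecast(eye, g, 13), g, atol=1e-12)

    def test_long_horizon_reaches_stationary(self, tiny_hmm_params):
        A = tiny_hmm_params.transition
        vals, vecs = np.linalg.eig(A.T)
        stat = np.real(vecs[:, np.argmax(np.real(vals))])
        stat = stat / stat.sum()
        out = hmm_forecast(tiny_hmm_params, np.array([1.0, 0.0]), 200)
        np.testing.assert_allclose(out, stat, atol=1e-6)

    def test_negative_horizon_rejected(self, tiny_hmm_params):
        with pytest.raises(ValueError):
            hmm_forecast(tiny_hmm_params, np.array([0.5, 0.5]), -1)

    def test_forecast_stays_on_simplex(self, tiny_hmm_params):
        g = np.array([0.2, 0.8])
        for h in range(10):
            out = hmm_forecast(tiny_hmm_params, g, h)
            assert np.all(out >= 0) and out.sum() == pytest.approx(1.0, abs=1e-12)


def test_json_round_trip(tmp_path, tiny_hmm_params):
    path = tmp_path / "model.json"
    tiny_hmm_params.to_json(path)
    loaded = HHMMParams.from_json(path)
    np.testing.assert_array_equal(loaded.transition, tiny_hmm_params.transition)
    np.testing.assert_array_equal(loaded.gauss_means, tiny_hmm_params.gauss_means)
    np.testing.assert_array_equal(loaded.bern_p, tiny_hmm_params.bern_p)
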